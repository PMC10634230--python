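"""Closed-form assay calculations: qPCR relative quantification and SEAP
reporter fold induction."""

from __future__ import annotations

import math


def ddct_fold(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative expression by the delta-delta-Ct method.

    Fold change = 2^-ddCt with
    ddCt = (Ct_target - Ct_reference)_test - (Ct_target - Ct_reference)_calibrator.
    """
    for ct in (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def relative_quantity_released(ct_target: float, ct_ref: float, R: float) -> float:
    """Relative quantity of a transcript released, 2^dCt x R.

    dCt is oriented as Ct_reference - Ct_target, so a more abundant target
    (lower target Ct) gives a larger output; R is the RNA-yield ratio of
    the treated (e.g. UV-irradiated) to the live condition and scales the
    result linearly.
    """
    if R <= 0:
        raise ValueError(f"RNA-yield ratio R must be positive, got {R}")
    return 2.0 ** (ct_ref - ct_target) * R


def fold_induction(
    absorbance_treated: float,
    absorbance_comparator: float,
    absorbance_untreated: float,
) -> float:
    """SEAP reporter fold induction, Delta_A / Delta_0.

    Delta_A = treated - untreated absorbance; Delta_0 = comparator (mock
    or inert-oligo) - untreated absorbance.  Undefined when the comparator
    equals the untreated baseline.
    """
    delta_0 = absorbance_comparator - absorbance_untreated
    if delta_0 == 0:
        raise ZeroDivisionError("comparator equals untreated baseline; fold undefined")
    return (absorbance_treated - absorbance_untreated) / delta_0
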