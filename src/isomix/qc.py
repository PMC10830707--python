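"""Quality control on C:N ratios and derived body-condition covariates.

C:N weight-percent ratios diagnose tissue composition: lizard tail tips (a
keratin/skin/connective-tissue composite) are expected in the 3.1-3.9 band,
and mixed proteinaceous/chitin arthropod preparations in 3.7-5.9.  Samples
slightly outside the tail band are flagged but retained — they are not
isotopically anomalous — while strongly divergent ratios fail.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .records import IsotopeRecord, LizardRecord

__all__ = ["qc_cn_ratio", "body_condition", "DegenerateDesignError"]

# lizard_tail bands: pass [3.1, 3.9]; flagged_retained (3.9, 4.5] and [2.9, 3.1);
# fail above 4.5 or below 2.9.  arthropod: pass [3.7, 5.9], else flagged_retained.
_TAIL_PASS = (3.1, 3.9)
_TAIL_FAIL_LOW, _TAIL_FAIL_HIGH = 2.9, 4.5
_ARTHROPOD_PASS = (3.7, 5.9)


class DegenerateDesignError(ValueError):
    """The regression design matrix is rank-deficient (e.g. all SVL identical)."""


def _flag_one(rec: IsotopeRecord) -> str:
    cn = rec.cn_ratio
    if rec.tissue == "lizard_tail":
        if cn is None:
            raise ValueError(f"{rec.sample_id}: lizard_tail sample lacks cn_ratio")
        if _TAIL_PASS[0] <= cn <= _TAIL_PASS[1]:
            return "pass"
        if cn > _TAIL_FAIL_HIGH or cn < _TAIL_FAIL_LOW:
            return "fail"
        return "flagged_retained"
    if rec.tissue == "arthropod":
        if cn is None:
            raise ValueError(f"{rec.sample_id}: arthropod sample lacks cn_ratio")
        if _ARTHROPOD_PASS[0] <= cn <= _ARTHROPOD_PASS[1]:
            return "pass"
        return "flagged_retained"
    # plants/algae carry no C:N QC rule
    return "pass"


def qc_cn_ratio(records: Sequence[IsotopeRecord]) -> List[IsotopeRecord]:
    """Return records with ``qc_flag`` set from the tissue-specific C:N bands.

    Pure per-record rule: idempotent and independent of record order.  Raises
    ``ValueError`` if a tissue that requires C:N lacks it.
    """
    return [rec.with_qc(_flag_one(rec)) for rec in records]


def body_condition(lizards: Sequence[LizardRecord], *, per_site: bool = False) -> List[LizardRecord]:
    """Set ``body_condition`` as the residual of OLS mass ~ SVL^3 (with intercept).

    The regression is fit over the supplied set, pooled across sites by
    default (``per_site=True`` refits within each site).  Residuals of an
    intercept model sum to zero, so condition is a within-set relative index
    of fat storage.  Requires >= 3 lizards with both SVL and mass.
    """
    if per_site:
        out: List[LizardRecord] = []
        for site in sorted({l.site for l in lizards}):
            out.extend(body_condition([l for l in lizards if l.site == site]))
        order = {l.sample_id: i for i, l in enumerate(lizards)}
        return sorted(out, key=lambda l: order[l.sample_id])

    usable = [l for l in lizards if l.svl is not None and l.mass is not None]
    if len(usable) < 3:
        raise ValueError("body_condition needs >= 3 lizards with svl and mass")
    svl3 = np.array([l.svl**3 for l in usable], dtype=float)
    mass = np.array([l.mass for l in usable], dtype=float)
    if np.ptp(svl3) == 0:
        raise DegenerateDesignError("all SVL values identical; mass ~ SVL^3 is degenerate")
    X = np.column_stack([np.ones_like(svl3), svl3])
    beta, *_ = np.linalg.lstsq(X, mass, rcond=None)
    resid = mass - X @ beta
    fitted = {l.sample_id: r for l, r in zip(usable, resid)}
    from dataclasses import replace
    return [replace(l, body_condition=fitted.get(l.sample_id)) for l in lizards]
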