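"""Candidate-gene selection for concentration-response screening.

A gene enters the modelling stage only if it is (i) statistically
significant — one-way ANOVA across the concentration groups with unadjusted
p < 0.001 — and (ii) biologically relevant: some treated concentration shows
a mean log2 fold change versus control of at least log2(1.5) ~ 0.585 in
magnitude, and the direction is unambiguous (no pair of concentrations
exceeding the threshold in opposite directions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = [
    "GeneProfile",
    "anova_pvalue",
    "relevance_flags",
    "select_genes",
    "FC_THRESHOLD",
    "ALPHA_DEFAULT",
]

logger = logging.getLogger(__name__)

#: log2(1.5): the minimal relevant absolute log2 fold change vs control.
FC_THRESHOLD = math.log2(1.5)
#: Unadjusted ANOVA significance cutoff.
ALPHA_DEFAULT = 0.001


@dataclass
class GeneProfile:
    """One gene's replicate responses grouped by concentration (0 = control)."""

    gene_id: str
    group_values: dict

    def groups(self) -> list:
        return [np.asarray(v, dtype=float) for v in self.group_values.values()]


def anova_pvalue(profile: GeneProfile) -> float:
    """Unadjusted one-way fixed-effects ANOVA F-test p-value.

    Degenerate profiles where every observation is identical (zero between-
    and within-group variance) return p = 1 by convention so that whole-matrix
    runs never abort; zero within-group variance with differing means gives
    p = 0 (infinite F).
    """
    groups = profile.groups()
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = sum(g.size for g in groups)
    k = len(groups)
    if n <= k:
        raise ValueError("zero within-group degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        return 1.0 if ssb == 0.0 else 0.0
    F = (ssb / (k - 1)) / (ssw / (n - k))
    return float(f_dist.sf(F, k - 1, n - k))


def relevance_flags(
    profile: GeneProfile, threshold: float = FC_THRESHOLD
) -> tuple:
    """Largest absolute log2 fold change vs control, and direction ambiguity.

    Returns ``(max_abs_fc, ambiguous)`` where the fold change of a treated
    concentration is the difference of its group mean from the control mean
    (values are already log2 expression) and ``ambiguous`` is True when one
    concentration exceeds +threshold while another falls below -threshold.
    """
    if 0.0 not in {float(c) for c in profile.group_values}:
        raise ValueError(f"gene {profile.gene_id}: control group (0) absent")
    control_mean = float(np.mean(profile.group_values[_control_key(profile)]))
    fcs = np.array(
        [
            float(np.mean(v)) - control_mean
            for c, v in profile.group_values.items()
            if float(c) != 0.0
        ]
    )
    if fcs.size == 0:
        return 0.0, False
    ambiguous = bool(np.any(fcs > threshold) and np.any(fcs < -threshold))
    return float(np.max(np.abs(fcs))), ambiguous


def _control_key(profile: GeneProfile):
    for c in profile.group_values:
        if float(c) == 0.0:
            return c
    raise ValueError("control group absent")


def select_genes(
    profiles,
    alpha: float = ALPHA_DEFAULT,
    threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Apply both filters to every gene.

    Returns the per-gene report with columns ``gene, pvalue, max_abs_fc,
    ambiguous, selected``; a gene is selected iff p < alpha, max |fc| >=
    threshold and the direction is unambiguous.  Per-gene computation errors
    demote the gene to not-selected with a logged warning instead of aborting
    the run.
    """
    rows = []
    for profile in profiles:
        try:
            p = anova_pvalue(profile)
            max_fc, ambiguous = relevance_flags(profile, threshold)
            selected = (p < alpha) and (max_fc >= threshold) and not ambiguous
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", profile.gene_id, exc)
            p, max_fc, ambiguous, selected = np.nan, np.nan, False, False
        rows.append(
            {
                "gene": profile.gene_id,
                "pvalue": p,
                "max_abs_fc": max_fc,
                "ambiguous": ambiguous,
                "selected": selected,
            }
        )
    return pd.DataFrame(rows)
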