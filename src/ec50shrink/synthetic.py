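"""Synthetic truth tables and expression matrices for end-to-end testing.

The real study derives per-gene truth curves from fits to an RMA-normalised
valproic-acid microarray experiment.  This module replaces that step with
configurable generative models so every downstream stage (filtering,
fitting, shrinkage, simulation) is exercisable without any data download:

* the true log-EC50 is drawn from either a single normal or a 5-component
  normal mixture whose default parameters reproduce the log-EC50 landscape
  estimated from the valproic-acid case study (a dominant mid-range
  component, two heavy-tail components, and two artefact components);
* slope magnitudes |b| default to [0.3, 5], spanning both the flat-slope
  regime (where shrinkage helps most) and steep, well-identified curves;
* the effect size d - c defaults to at least log2(1.5) so generated genes
  are biologically relevant by construction, and the baseline c spans a
  typical RMA log2 expression range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import VPA_DESIGN, ConcentrationDesign, LL4Params
from .plasmode import simulate_dataset

__all__ = [
    "VPA_ETILDE_MIXTURE",
    "TruthGeneratorConfig",
    "generate_truths",
    "generate_expression_matrix",
    "mixture_mean",
]

#: 5-component normal mixture describing the cross-gene distribution of the
#: true log-EC50 in the valproic-acid case study (weights, means, sds).
VPA_ETILDE_MIXTURE = {
    "weights": (0.570, 0.042, 0.093, 0.002, 0.294),
    "means": (6.225, 5.128, 9.755, 19.092, 7.458),
    "sds": (0.352, 0.150, 2.643, 32.145, 1.399),
}


def mixture_mean(mixture: dict) -> float:
    """Analytic mean of a normal mixture, sum(w_i * mu_i)."""
    w = np.asarray(mixture["weights"], dtype=float)
    m = np.asarray(mixture["means"], dtype=float)
    return float(w @ m / w.sum())


@dataclass(frozen=True)
class TruthGeneratorConfig:
    """Generative model for per-gene 4pLL truth parameters.

    ``e_tilde_model`` is ``"normal"`` (uses ``mu0``/``tau2``) or
    ``"mixture"`` (uses ``mixture``, defaulting to the case-study values).
    ``b_range`` bounds |b|; ``b_sign`` is ``"random"``, ``"positive"`` or
    ``"negative"``.  ``effect_range`` bounds d - c (> 0), ``baseline_range``
    bounds c (log2 expression units).
    """

    n_genes: int
    e_tilde_model: str = "mixture"
    mu0: float = 6.2
    tau2: float = 0.35**2
    mixture: dict = field(default_factory=lambda: dict(VPA_ETILDE_MIXTURE))
    b_range: tuple = (0.3, 5.0)
    b_sign: str = "random"
    effect_range: tuple = (0.585, 3.0)
    baseline_range: tuple = (5.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.e_tilde_model not in ("normal", "mixture"):
            raise ValueError(f"unknown e_tilde_model {self.e_tilde_model!r}")
        for name in ("b_range", "effect_range", "baseline_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")
        if self.effect_range[0] <= 0:
            raise ValueError("effect_range lower bound must be > 0")
        if self.b_range[0] < 0:
            raise ValueError("b_range bounds |b| and must be non-negative")
        if self.b_sign not in ("random", "positive", "negative"):
            raise ValueError(f"unknown b_sign {self.b_sign!r}")
        if self.e_tilde_model == "normal" and self.tau2 <= 0:
            raise ValueError("tau2 must be > 0")


def _draw_e_tilde(cfg: TruthGeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.e_tilde_model == "normal":
        return rng.normal(cfg.mu0, np.sqrt(cfg.tau2), size=cfg.n_genes)
    w = np.asarray(cfg.mixture["weights"], dtype=float)
    w = w / w.sum()
    comp = rng.choice(w.size, size=cfg.n_genes, p=w)
    means = np.asarray(cfg.mixture["means"], dtype=float)
    sds = np.asarray(cfg.mixture["sds"], dtype=float)
    return rng.normal(means[comp], sds[comp])


def generate_truths(config: TruthGeneratorConfig) -> pd.DataFrame:
    """Draw a per-gene truth table with columns ``gene, b, c, d, e_tilde``.

    Deterministic given ``config.seed``; the log-EC50 and the curve-shape
    parameters are drawn independently.
    """
    rng = np.random.default_rng(config.seed)
    e_tilde = _draw_e_tilde(config, rng)
    b_mag = rng.uniform(*config.b_range, size=config.n_genes)
    if config.b_sign == "random":
        sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    else:
        sign = 1.0 if config.b_sign == "positive" else -1.0
    effect = rng.uniform(*config.effect_range, size=config.n_genes)
    c = rng.uniform(*config.baseline_range, size=config.n_genes)
    return pd.DataFrame(
        {
            "gene": [f"gene{i:05d}" for i in range(config.n_genes)],
            "b": b_mag * sign,
            "c": c,
            "d": c + effect,
            "e_tilde": e_tilde,
        }
    )


def generate_expression_matrix(
    truths: pd.DataFrame,
    design: ConcentrationDesign = VPA_DESIGN,
    noise_sd: float = 0.1,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple:
    """Simulate an expression matrix + sample sheet from a truth table.

    Returns ``(matrix, sample_sheet)`` where ``matrix`` is genes x samples
    (first column ``gene``) and ``sample_sheet`` maps sample names to
    concentrations — exactly the on-disk format the command-line pipeline
    consumes.  When ``out_dir`` is given, writes ``expression.tsv``,
    ``samples.tsv`` and ``truths.tsv`` there.

    Noise uses a per-gene substream of ``seed`` so adding genes never
    perturbs existing genes' values.
    """
    x = design.expand()
    sample_names = []
    counts: dict = {}
    for conc in x:
        counts[conc] = counts.get(conc, 0) + 1
        sample_names.append(f"s{len(sample_names):02d}_c{conc:g}_r{counts[conc]}")
    rows = {}
    for g, row in enumerate(truths.itertuples()):
        truth = LL4Params(row.b, row.c, row.d, row.e_tilde)
        rng = np.random.default_rng([seed, g])
        _, y = simulate_dataset(truth, design, noise_sd, rng)
        rows[row.gene] = y
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=sample_names)
    matrix.index.name = "gene"
    matrix = matrix.reset_index()
    sheet = pd.DataFrame({"sample": sample_names, "concentration": x})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out / "expression.tsv", sep="\t", index=False)
        sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
        truths.to_csv(out / "truths.tsv", sep="\t", index=False)
    return matrix, sheet
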