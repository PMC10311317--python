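"""Interpretation reports read directly off trained model parameters.

Because every layer of the architecture maps to a biological quantity, no
attribution machinery is needed: the final-layer coefficients are per-output
motif effects, the pooling temperatures say whether a motif acts through its
strongest site or through site counting, and the interaction matrix records
which motifs modulate which.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import KernelBank, MotifLibrary, SimilarityMatrix, information_content, pwm_similarity
from .optim import PathResult

__all__ = [
    "normalize_coefficients",
    "inclusion_ratio",
    "interaction_influence",
    "pooling_ic_report",
    "redundancy_vs_lambda",
    "kernel_drift",
    "ImportanceReport",
]


def normalize_coefficients(coef: np.ndarray) -> np.ndarray:
    """Rescale each output's coefficients to [-1, 1] without breaking
    sparsity: rows are divided by their max |value|; zeros stay exact zeros
    and all-zero rows are left untouched."""
    coef = np.asarray(coef, dtype=float)
    if not np.all(np.isfinite(coef)):
        raise ValueError("coefficients must be finite")
    peak = np.abs(coef).max(axis=1, keepdims=True)
    safe = np.where(peak > 0, peak, 1.0)
    return coef / safe


def inclusion_ratio(per_fold_coefs: list[np.ndarray], k_top: int = 10) -> np.ndarray:
    """Fraction of folds in which each motif ranks among the top ``k_top``
    absolute coefficients for each output. Ties (e.g. exact zeros after
    thresholding) break by stable motif index order."""
    if len(per_fold_coefs) == 0:
        raise ValueError("need at least one fold")
    c, m = per_fold_coefs[0].shape
    if k_top > m:
        raise ValueError(f"k_top={k_top} exceeds motif count {m}")
    counts = np.zeros((c, m))
    for coef in per_fold_coefs:
        if coef.shape != (c, m):
            raise ValueError("fold coefficient matrices differ in shape")
        # stable mergesort on -|coef| keeps index order among ties
        order = np.argsort(-np.abs(coef), axis=1, kind="stable")
        top = order[:, :k_top]
        for out in range(c):
            counts[out, top[out]] += 1
    return counts / len(per_fold_coefs)


def interaction_influence(A: np.ndarray) -> np.ndarray:
    """Total influence a motif exerts on other motifs' gates: the column
    sums of |A|."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("interaction matrix must be square")
    return np.abs(A).sum(axis=0)


def pooling_ic_report(
    pool: np.ndarray, lib: MotifLibrary, background=None
) -> tuple[pd.DataFrame, float, bool]:
    """Pair each motif's pooling temperature with its information content
    and report the Spearman rank correlation between the two.

    Returns (table, correlation, degenerate). A constant pooling vector has
    no defined rank correlation; it is reported as 0 with the degenerate
    flag set.
    """
    pool = np.asarray(pool, dtype=float)
    if len(pool) != len(lib):
        raise ValueError("pooling vector length does not match library")
    ic = np.array([information_content(p, background) for p in lib])
    table = pd.DataFrame({"motif": lib.names, "pool": pool, "ic": ic})
    degenerate = np.all(pool == pool[0]) or np.all(ic == ic[0])
    if degenerate:
        return table, 0.0, True
    rho = float(stats.spearmanr(pool, ic).statistic)
    return table, rho, False


def redundancy_vs_lambda(
    path: PathResult, similarity: SimilarityMatrix
) -> pd.DataFrame:
    """Per penalty strength: the median, over selected motifs, of each
    selected motif's maximum similarity to the other selected motifs.

    Single-motif (or empty) supports have no pairwise similarity and are
    flagged undefined (NaN median).
    """
    oriented = similarity.oriented()
    rows = []
    for i, lam in enumerate(path.lambdas):
        sel = path.support(i)
        if len(sel) < 2:
            rows.append({"lambda": lam, "support_size": len(sel),
                         "median_max_similarity": np.nan, "defined": False})
            continue
        sub = oriented[np.ix_(sel, sel)].copy()
        np.fill_diagonal(sub, -np.inf)
        per_motif_max = sub.max(axis=1)
        med = float(np.median(per_motif_max))
        if not similarity.higher_is_similar:
            med = -med  # report on the original (log10 E-value) scale
        rows.append({"lambda": lam, "support_size": len(sel),
                     "median_max_similarity": med, "defined": True})
    return pd.DataFrame(rows)


def kernel_drift(
    before: KernelBank, after: KernelBank, lib: MotifLibrary
) -> tuple[pd.DataFrame, float]:
    """Compare fine-tuned kernels against their initial PWM kernels.

    For each motif: the per-entry mean squared difference over the motif's
    valid positions, and the name of the *initial* kernel most similar to
    the fine-tuned one (ungapped correlation). Returns the per-motif table
    and the fraction of motifs whose nearest initial kernel is themselves.
    """
    if before.weights.shape != after.weights.shape:
        raise ValueError("kernel banks differ in shape")
    if not np.array_equal(before.valid_width, after.valid_width):
        raise ValueError("kernel banks differ in motif widths or order")
    if list(lib.names) and len(lib) != before.m:
        raise ValueError("library size does not match kernel banks")
    rows = []
    self_nearest = 0
    initial = [
        before.weights[j, :, : before.valid_width[j]].T for j in range(before.m)
    ]
    for i in range(before.m):
        w = int(before.valid_width[i])
        diff = after.weights[i, :, :w] - before.weights[i, :, :w]
        mse = float((diff**2).mean())
        tuned = after.weights[i, :, :w].T
        sims = [pwm_similarity(tuned, init) for init in initial]
        nearest = int(np.argmax(sims))
        if nearest == i:
            self_nearest += 1
        rows.append(
            {"motif": lib.names[i], "mse": mse, "nearest_initial": lib.names[nearest]}
        )
    return pd.DataFrame(rows), self_nearest / before.m


@dataclass
class ImportanceReport:
    """Bundle of all parameter-derived reports for one trained model."""

    normalized_coef: pd.DataFrame  # outputs x motifs in [-1, 1]
    top_k: dict[str, list[str]]
    inclusion: pd.DataFrame | None
    pooling_ic: pd.DataFrame
    pooling_ic_rho: float
    interaction: pd.DataFrame | None

    @classmethod
    def from_model(
        cls,
        model,
        lib: MotifLibrary,
        output_names: list[str],
        per_fold_coefs: list[np.ndarray] | None = None,
        k_top: int = 10,
    ) -> "ImportanceReport":
        coef = model.params["coef"].data
        norm = normalize_coefficients(coef)
        norm_df = pd.DataFrame(norm, index=output_names, columns=lib.names)
        k_eff = min(k_top, len(lib))
        order = np.argsort(-np.abs(coef), axis=1, kind="stable")
        top = {
            out: [lib.names[j] for j in order[i, :k_eff]]
            for i, out in enumerate(output_names)
        }
        incl = None
        if per_fold_coefs:
            ratios = inclusion_ratio(per_fold_coefs, k_top=k_eff)
            incl = pd.DataFrame(ratios, index=output_names, columns=lib.names)
        table, rho, _ = pooling_ic_report(model.params["pool"].data, lib)
        inter = None
        if model.config.use_interaction:
            infl = interaction_influence(model.params["interaction"].data)
            inter = pd.DataFrame({"motif": lib.names, "influence": infl})
        return cls(norm_df, top, incl, table, rho, inter)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.normalized_coef.to_csv(out / "coefficients_normalized.tsv", sep="\t")
        pd.DataFrame(
            [(o, i + 1, m) for o, ms in self.top_k.items() for i, m in enumerate(ms)],
            columns=["output", "rank", "motif"],
        ).to_csv(out / "top_motifs.tsv", sep="\t", index=False)
        if self.inclusion is not None:
            self.inclusion.to_csv(out / "inclusion_ratio.tsv", sep="\t")
        self.pooling_ic.to_csv(out / "pooling_vs_ic.tsv", sep="\t", index=False)
        if self.interaction is not None:
            self.interaction.to_csv(out / "interaction_influence.tsv", sep="\t", index=False)
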