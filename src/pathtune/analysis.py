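"""Multicriteria decision support on Pareto libraries.

Level diagrams plot, for every Pareto solution, the p-norm of its
min–max-normalized objective vector (a common y-value across panels)
against each objective and each decision variable, making trade-off
regimes visible at a glance.  This module computes those norms, selects
representative designs (per-objective extremes plus the minimum-norm
compromise), summarizes pairwise objective trade-offs, and renders
static level-diagram and front plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

CSV_FLOAT_FORMAT = "%.17g"  # lossless float round-trips


def pnorm_levels(front: np.ndarray, p: float = 2.0) -> np.ndarray:
    """Per-solution p-norm of min–max-normalized objectives.

    ``front`` is (n_solutions, n_objectives); ``p`` is >= 1 or ``np.inf``.
    A degenerate objective (max == min across the front) normalizes to 0
    with a warning.
    """
    J = np.atleast_2d(np.asarray(front, float))
    if J.size == 0:
        raise ValueError("front must be nonempty")
    if not (p >= 1):
        raise ValueError("p must be >= 1 (np.inf allowed)")
    ideal = J.min(axis=0)
    nadir = J.max(axis=0)
    span = nadir - ideal
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"degenerate objective(s) {np.where(degenerate)[0].tolist()} "
            "normalized to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    Jn = np.zeros_like(J)
    ok = ~degenerate
    Jn[:, ok] = (J[:, ok] - ideal[ok]) / span[ok]
    return np.linalg.norm(Jn, ord=p, axis=1)


@dataclass
class ParetoTable:
    """A Pareto library with level-diagram norms and its normalization record."""

    table: pd.DataFrame                 # solution_id, theta_*, objectives, norm
    objective_names: Tuple[str, ...]
    theta_names: Tuple[str, ...]
    p: float
    ideal: np.ndarray
    nadir: np.ndarray

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        objective_names: Optional[Sequence[str]] = None,
        p: float = 2.0,
    ) -> "ParetoTable":
        df = df.copy().reset_index(drop=True)
        if "solution_id" not in df.columns:
            df.insert(0, "solution_id", np.arange(len(df)))
        theta_names = tuple(
            c[len("theta_"):] for c in df.columns if c.startswith("theta_")
        )
        if objective_names is None:
            reserved = {"solution_id", "violation", "feasible", "norm"}
            objective_names = tuple(
                c
                for c in df.columns
                if not c.startswith("theta_") and c not in reserved
            )
        objective_names = tuple(objective_names)
        if not objective_names:
            raise ValueError("no objective columns found")
        J = df[list(objective_names)].to_numpy(float)
        df["norm"] = pnorm_levels(J, p)
        return cls(
            table=df,
            objective_names=objective_names,
            theta_names=theta_names,
            p=p,
            ideal=J.min(axis=0),
            nadir=J.max(axis=0),
        )

    @classmethod
    def from_archive_result(cls, result, p: float = 2.0) -> "ParetoTable":
        return cls.from_frame(
            result.archive_frame(), objective_names=result.objective_names, p=p
        )

    @classmethod
    def from_csv(cls, path, p: float = 2.0, objective_names=None) -> "ParetoTable":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed archive CSV {path}: {exc}") from exc
        df = df.drop(columns=["norm"], errors="ignore")
        return cls.from_frame(df, objective_names=objective_names, p=p)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    def objectives(self) -> np.ndarray:
        return self.table[list(self.objective_names)].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


def select_representatives(pt: ParetoTable) -> pd.DataFrame:
    """Per-objective best solutions plus the minimum-norm compromise.

    Deterministic: ties break on the smaller solution id.  Rows are
    labelled by role; a solution filling several roles appears once per
    role but duplicates share the same solution id.
    """
    df = pt.table
    order = df.sort_values("solution_id").index
    roles: List[Tuple[str, int]] = []
    for name in pt.objective_names:
        sub = df.loc[order]
        roles.append((f"min_{name}", int(sub[name].idxmin())))
    sub = df.loc[order]
    roles.append(("compromise", int(sub["norm"].idxmin())))
    rows = []
    for role, idx in roles:
        row = df.loc[idx].to_dict()
        row["role"] = role
        rows.append(row)
    out = pd.DataFrame(rows)
    cols = ["role"] + [c for c in df.columns]
    return out[cols].reset_index(drop=True)


def tradeoff_stats(pt: ParetoTable) -> Dict[str, object]:
    """Pairwise Spearman rank correlations between objectives.

    For a strictly non-dominated two-objective front the correlation is
    exactly -1.  Degenerate (constant) objectives are flagged with a
    ``None`` correlation.
    """
    if len(pt) < 3:
        raise ValueError("need at least 3 solutions for trade-off statistics")
    J = pt.objectives()
    out: Dict[str, object] = {"n_solutions": len(pt)}
    corr = {}
    for i, ni in enumerate(pt.objective_names):
        for j in range(i + 1, len(pt.objective_names)):
            nj = pt.objective_names[j]
            if np.ptp(J[:, i]) == 0 or np.ptp(J[:, j]) == 0:
                corr[f"{ni}:{nj}"] = None
            else:
                rho = stats.spearmanr(J[:, i], J[:, j]).statistic
                corr[f"{ni}:{nj}"] = float(rho)
    out["spearman"] = corr
    return out


def label_regimes(pt: ParetoTable, k: int = 3, seed: int = 0) -> np.ndarray:
    """Label trade-off regimes by k-means on normalized objectives.

    A plotting/reporting convenience only — never used in optimization.
    Deterministic given the seed; returns an integer label per solution,
    with clusters ordered by their centroid norm.
    """
    J = pt.objectives()
    ideal, nadir = J.min(axis=0), J.max(axis=0)
    span = np.where(nadir > ideal, nadir - ideal, 1.0)
    Z = (J - ideal) / span
    k = min(k, len(pt))
    rng = np.random.default_rng(seed)
    centers = Z[rng.choice(len(Z), size=k, replace=False)]
    labels = np.zeros(len(Z), dtype=int)
    for _ in range(50):
        d = np.linalg.norm(Z[:, None, :] - centers[None, :, :], axis=2)
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            if np.any(labels == c):
                centers[c] = Z[labels == c].mean(axis=0)
    order = np.argsort(np.linalg.norm(centers, axis=1))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def level_diagram_plots(pt: ParetoTable, outdir) -> List[Path]:
    """One level-diagram panel per objective and per decision variable."""
    plt = _mpl()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    norm = pt.table["norm"].to_numpy()
    panels = [(name, pt.table[name].to_numpy()) for name in pt.objective_names]
    panels += [
        (f"theta_{name}", pt.table[f"theta_{name}"].to_numpy())
        for name in pt.theta_names
    ]
    for name, x in panels:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(x, norm, "o", ms=4)
        ax.set_xlabel(name)
        ax.set_ylabel(f"{pt.p:g}-norm of normalized objectives")
        ax.set_title(f"Level diagram: {name}")
        fig.tight_layout()
        path = outdir / f"level_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def front_plot(pt: ParetoTable, outdir, fname: str = "pareto_front.png") -> Path:
    """2-D front scatter; a third objective, if present, sets marker size."""
    plt = _mpl()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    J = pt.objectives()
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    if J.shape[1] >= 3:
        j3 = J[:, 2]
        span = np.ptp(j3)
        size = 20 + 180 * (j3 - j3.min()) / (span if span > 0 else 1.0)
        ax.scatter(J[:, 0], J[:, 1], s=size, alpha=0.6, edgecolor="k", linewidth=0.4)
        ax.set_title(f"Pareto front (marker size: {pt.objective_names[2]})")
    else:
        ax.scatter(J[:, 0], J[:, 1], s=25)
        ax.set_title("Pareto front")
    ax.set_xlabel(pt.objective_names[0])
    ax.set_ylabel(pt.objective_names[1])
    fig.tight_layout()
    path = outdir / fname
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
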