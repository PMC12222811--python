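"""Scaling-law statistics over per-plasmid copy-number tables.

Input is a tidy table with one row per plasmid: ``genome_id,
replicon_id, length_bp, chromosome_length_bp, pcn``.  The analyses:

* **normalization** — plasmid length divided by the longest chromosome's
  length, putting all genomes on one axis;
* **segmented regression** — a continuous two-segment (broken-line)
  least-squares model in log10-log10 space,
  ``y = a + b1 x + b2 max(0, x - c)``, with the breakpoint ``c``
  estimated by profiling the residual sum of squares over a quantile
  grid and refining by golden-section search.  Reported slopes are
  ``b1`` (below the break) and ``b1 + b2`` (above);
* **AIC model comparison** — the segmented model against ordinary linear
  and quadratic fits, all under the Gaussian form
  ``AIC = n ln(RSS/n) + 2p``;
* **K = 2 clustering** of log10 plasmid length (the size distribution is
  bimodal: small multicopy plasmids vs large low-copy plasmids);
* **intragenomic census** — per-genome Pearson correlation between
  plasmid length and copy number, counted negative vs positive;
* **DNA-content scaling** — the same segmented machinery on
  ``log10(pcn x length / chromosome_length)``; under an exact inverse
  (slope −1) law this response would be flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.cluster import KMeans

REQUIRED_COLUMNS = ("genome_id", "replicon_id", "length_bp", "chromosome_length_bp", "pcn")


def normalize_length(length, chromosome_length=None):
    """Plasmid length as a fraction of its genome's longest chromosome.

    Accepts either two scalars/arrays or a single record object with
    ``length`` / ``chromosome_length`` attributes.  Result lies in (0, 1]
    for filtered data.
    """
    if chromosome_length is None:
        rec = length
        return rec.length / rec.chromosome_length
    return np.asarray(length, dtype=float) / np.asarray(chromosome_length, dtype=float)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _gaussian_aic(rss: float, n: int, p: int) -> float:
    return n * np.log(rss / n) + 2 * p


def _adj_r2(rss: float, tss: float, n: int, n_params: int) -> float:
    # n_params counts all mean-structure parameters including intercept
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


@dataclass
class SegmentedResults:
    """Fitted continuous broken-line model in log-log space."""

    intercept: float
    slope1: float
    slope2: float
    breakpoint: float
    adj_r2: float
    aic: float
    rss: float
    n: int
    breakpoint_supported: bool

    @property
    def params(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope1": self.slope1,
            "slope2": self.slope2,
            "breakpoint": self.breakpoint,
        }

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        b2 = self.slope2 - self.slope1
        return self.intercept + self.slope1 * x + b2 * np.maximum(0.0, x - self.breakpoint)

    def summary(self) -> str:
        flag = "" if self.breakpoint_supported else "   [no breakpoint support]"
        return "\n".join(
            [
                "Segmented (broken-line) regression, log10-log10",
                "=" * 52,
                f"n observations     {self.n}",
                f"slope below break  {self.slope1:+.4f}",
                f"slope above break  {self.slope2:+.4f}",
                f"breakpoint (log10) {self.breakpoint:+.4f}"
                f"  ({100 * 10 ** self.breakpoint:.2f}% of chromosome if x is "
                "normalized length)" + flag,
                f"intercept          {self.intercept:+.4f}",
                f"adjusted R^2       {self.adj_r2:.4f}",
                f"AIC (Gaussian)     {self.aic:.1f}",
                "=" * 52,
            ]
        )


class SegmentedRegression:
    """Two-segment continuous piecewise-linear model of y on x.

    Breakpoint estimation profiles RSS(c) on a 513-point grid over the
    1%–99% interior quantiles of x and polishes the best grid cell with
    golden-section (bounded scalar) search.  Candidates leaving fewer
    than 3 distinct x values on either side are excluded.
    """

    GRID_POINTS = 513

    def __init__(self, x: Sequence[float], y: Sequence[float]) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if self.x.size < 10:
            raise ValueError("need at least 10 observations")
        if np.unique(self.x).size < 2:
            raise ValueError("x is degenerate (fewer than 2 distinct values)")

    def _rss_at(self, c: float) -> float:
        X = np.column_stack(
            [np.ones_like(self.x), self.x, np.maximum(0.0, self.x - c)]
        )
        _, rss = _ols(X, self.y)
        return rss

    def fit(self) -> SegmentedResults:
        x, y = self.x, self.y
        xs = np.unique(x)
        # candidate breakpoints must keep >= 3 distinct x on both sides
        if xs.size >= 6:
            lo, hi = xs[2], xs[-3]
        else:
            lo, hi = xs[0], xs[-1]
        qgrid = np.quantile(x, np.linspace(0.01, 0.99, self.GRID_POINTS))
        grid = np.unique(np.clip(qgrid, lo, hi))
        rss_grid = np.array([self._rss_at(c) for c in grid])
        best = int(np.argmin(rss_grid))
        bracket_lo = grid[max(best - 1, 0)]
        bracket_hi = grid[min(best + 1, grid.size - 1)]
        if bracket_hi > bracket_lo:
            res = minimize_scalar(
                self._rss_at,
                bounds=(bracket_lo, bracket_hi),
                method="bounded",
                options={"xatol": 1e-10},
            )
            c = float(res.x)
            if self._rss_at(c) > rss_grid[best]:
                c = float(grid[best])
        else:
            c = float(grid[best])

        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - c)])
        beta, rss = _ols(X, y)
        a, b1, b2 = (float(v) for v in beta)
        n = x.size
        tss = float(((y - y.mean()) ** 2).sum())
        supported = not (
            np.isclose(c, grid[0]) or np.isclose(c, grid[-1])
        )
        return SegmentedResults(
            intercept=a,
            slope1=b1,
            slope2=b1 + b2,
            breakpoint=c,
            adj_r2=_adj_r2(rss, tss, n, n_params=4),
            aic=_gaussian_aic(rss, n, p=5),
            rss=rss,
            n=n,
            breakpoint_supported=supported,
        )


def fit_segmented(x: Sequence[float], y: Sequence[float]) -> SegmentedResults:
    """Fit the continuous two-segment model (see SegmentedRegression)."""
    return SegmentedRegression(x, y).fit()


def compare_models(x: Sequence[float], y: Sequence[float]) -> pd.DataFrame:
    """AIC table for linear, quadratic and segmented fits of y on x.

    One Gaussian AIC convention throughout (``n ln(RSS/n) + 2p`` with p
    counting mean parameters plus the error variance), so the ΔAIC
    ranking is meaningful.  Sorted ascending by AIC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    tss = float(((y - y.mean()) ** 2).sum())
    rows = []

    X1 = np.column_stack([np.ones_like(x), x])
    _, rss1 = _ols(X1, y)
    rows.append(("linear", _gaussian_aic(rss1, n, 3), _adj_r2(rss1, tss, n, 2), rss1, 3))

    X2 = np.column_stack([np.ones_like(x), x, x**2])
    _, rss2 = _ols(X2, y)
    rows.append(("quadratic", _gaussian_aic(rss2, n, 4), _adj_r2(rss2, tss, n, 3), rss2, 4))

    seg = fit_segmented(x, y)
    rows.append(("segmented", seg.aic, seg.adj_r2, seg.rss, 5))

    table = pd.DataFrame(
        rows, columns=["model", "aic", "adj_r2", "rss", "n_params"]
    ).sort_values("aic", ignore_index=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


@dataclass
class ClusterSummary:
    """K = 2 size clustering of plasmids, labeled small/large."""

    labels: np.ndarray  # "small" | "large" per record
    table: pd.DataFrame  # per-cluster count + pcn/length stats
    boundary_log10_length: float
    singleton: bool

    def summary(self) -> str:
        return self.table.to_string()


def kmeans_two(
    records: pd.DataFrame, seed: int = 0, n_init: int = 25
) -> ClusterSummary:
    """1-D K-means (K=2) on log10 plasmid length.

    Log scale makes the small-plasmid mode visible to squared-error
    clustering.  Clusters are relabeled small/large by mean length; the
    reported boundary is the midpoint between the extreme members of the
    two clusters.
    """
    lengths = records["length_bp"].to_numpy(dtype=float)
    if np.unique(lengths).size < 2:
        raise ValueError("need at least 2 distinct plasmid lengths")
    feat = np.log10(lengths).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed).fit(feat)
    means = [feat[km.labels_ == c].mean() for c in (0, 1)]
    small_cluster = int(np.argmin(means))
    labels = np.where(km.labels_ == small_cluster, "small", "large")

    stats = []
    for name in ("small", "large"):
        sel = labels == name
        sub = records.loc[sel]
        stats.append(
            {
                "cluster": name,
                "n": int(sel.sum()),
                "pcn_mean": sub["pcn"].mean(),
                "pcn_sd": sub["pcn"].std(ddof=1),
                "pcn_min": sub["pcn"].min(),
                "pcn_max": sub["pcn"].max(),
                "length_mean": sub["length_bp"].mean(),
                "length_sd": sub["length_bp"].std(ddof=1),
                "length_min": sub["length_bp"].min(),
                "length_max": sub["length_bp"].max(),
            }
        )
    table = pd.DataFrame(stats).set_index("cluster")
    hi_small = lengths[labels == "small"].max()
    lo_large = lengths[labels == "large"].min()
    boundary = (np.log10(hi_small) + np.log10(lo_large)) / 2
    singleton = min(int((labels == "small").sum()), int((labels == "large").sum())) == 1
    return ClusterSummary(
        labels=labels, table=table, boundary_log10_length=float(boundary),
        singleton=singleton,
    )


def intragenomic_correlations(
    records: pd.DataFrame, min_plasmids: int = 2
) -> dict:
    """Census of within-genome length–copy-number Pearson correlations.

    Only genomes with at least ``min_plasmids`` plasmids enter.  Genomes
    with zero variance in length or copy number (r undefined) are
    excluded and counted separately.
    """
    n_negative = n_positive = n_zero = n_undefined = 0
    r_neg: list[float] = []
    r_pos: list[float] = []
    for _, grp in records.groupby("genome_id"):
        if len(grp) < min_plasmids:
            continue
        x = grp["length_bp"].to_numpy(dtype=float)
        y = grp["pcn"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_undefined += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r < 0:
            n_negative += 1
            r_neg.append(r)
        elif r > 0:
            n_positive += 1
            r_pos.append(r)
        else:
            n_zero += 1
    return {
        "min_plasmids": min_plasmids,
        "n_genomes": n_negative + n_positive + n_zero + n_undefined,
        "n_negative": n_negative,
        "n_positive": n_positive,
        "n_zero": n_zero,
        "n_undefined": n_undefined,
        "mean_r_negative": float(np.mean(r_neg)) if r_neg else float("nan"),
        "mean_r_positive": float(np.mean(r_pos)) if r_pos else float("nan"),
    }


def scaling_fit(records: pd.DataFrame, normalized: bool = True) -> SegmentedResults:
    """Segmented fit of log10 PCN on log10 (normalized or raw) length."""
    if normalized:
        x = np.log10(normalize_length(records["length_bp"], records["chromosome_length_bp"]))
    else:
        x = np.log10(records["length_bp"].to_numpy(dtype=float))
    y = np.log10(records["pcn"].to_numpy(dtype=float))
    return fit_segmented(x, y)


def dna_content_scaling(records: pd.DataFrame) -> SegmentedResults:
    """Segmented fit of log10 normalized plasmid DNA content.

    Response: ``log10(pcn x length / chromosome_length)`` — plasmid DNA
    mass per chromosome copy, as a fraction of chromosome mass — against
    log10 normalized length.  If copy number scaled exactly as 1/length,
    both slopes would be 0; in general content-slope = 1 + pcn-slope.
    """
    norm = normalize_length(records["length_bp"], records["chromosome_length_bp"])
    x = np.log10(norm)
    y = np.log10(records["pcn"].to_numpy(dtype=float) * norm)
    return fit_segmented(x, y)


def load_plasmid_table(path) -> pd.DataFrame:
    """Read the per-plasmid TSV (columns REQUIRED_COLUMNS)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plasmid table missing columns: {sorted(missing)}")
    return df
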