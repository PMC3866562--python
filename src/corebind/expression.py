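"""Two-colour expression normalization and differential-expression calls.

This module targets the awkward regime where the majority of genes
genuinely change expression, so global centring (median or quantile over
all genes) is biased.  Normalization is instead anchored on a
rank-invariant gene set: genes whose between-channel ranks are stable on
every array.  A locally weighted regression of M on A fitted over that set
only is subtracted from all genes.

M = log2(sample/reference), A = mean log2 intensity.  Dye-swap replicates
carry M with the opposite sign and are re-oriented before any analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class ArrayChannelData:
    """One array's per-gene M (and optionally A) values."""

    array_id: str
    genes: np.ndarray  # gene ids, shared ordering across arrays
    M: np.ndarray
    A: Optional[np.ndarray] = None
    dye_swapped: bool = False

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.M = np.asarray(self.M, dtype=float)
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float)
        if len(self.M) != len(self.genes):
            raise ValueError("M and gene vectors differ in length")
        if self.A is not None and len(self.A) != len(self.genes):
            raise ValueError("A and gene vectors differ in length")


@dataclass
class NormConfig:
    """Tuning constants of the rank-invariant normalization.

    rank_diff_threshold: maximal allowed separation of the two channel
    intensities of a gene, measured as the fraction of the pooled
    two-channel intensity distribution lying between them, per array.
    max_abs_m: absolute cap on |M| (after re-centring) for candidates,
    guarding the intensity tails where rank separation is
    undiscriminating.  smoother_span: lowess span.  convergence: stop
    iterating once the invariant set changes by less than this fraction.
    """

    rank_diff_threshold: float = 0.05
    max_abs_m: float = 0.5
    max_iterations: int = 10
    smoother_span: float = 0.4
    convergence: float = 0.01
    min_invariant: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.rank_diff_threshold < 1:
            raise ValueError("rank_diff_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# shared numeric utilities


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a genes x arrays matrix.

    After normalization every column has the same sorted value vector: the
    per-rank mean over columns.  Tied values within a column receive the
    mean of their tied-rank targets.  Missing values (NaN) are excluded
    and restored as NaN; columns with missing values are mapped through
    quantile interpolation of the reference distribution.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 arrays (columns)")
    n_genes, n_arrays = values.shape
    grid = np.linspace(0.0, 1.0, n_genes)
    # reference distribution: mean of per-column quantile curves
    ref = np.zeros(n_genes)
    for j in range(n_arrays):
        col = values[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            raise ValueError(f"column {j} is entirely missing")
        q = np.linspace(0.0, 1.0, obs.size)
        ref += np.interp(grid, q, obs)
    ref /= n_arrays

    out = np.full_like(values, np.nan)
    for j in range(n_arrays):
        col = values[:, j]
        mask = ~np.isnan(col)
        obs = col[mask]
        order = np.argsort(obs, kind="stable")
        g = obs.size
        targets_sorted = np.interp(np.linspace(0.0, 1.0, g), grid, ref)
        assigned = np.empty(g)
        # walk runs of tied values, assigning the mean of their targets
        i = 0
        sorted_vals = obs[order]
        while i < g:
            k = i
            while k + 1 < g and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            assigned[order[i : k + 1]] = targets_sorted[i : k + 1].mean()
            i = k + 1
        out[mask, j] = assigned
    return out


def orient_dye_swaps(arrays: Sequence[ArrayChannelData]) -> list[ArrayChannelData]:
    """Negate M on dye-swapped arrays (A unchanged); flags are cleared."""
    out = []
    for a in arrays:
        if a.dye_swapped:
            out.append(replace(a, M=-a.M, dye_swapped=False))
        else:
            out.append(replace(a))
    return out


def _lowess_curve(x: np.ndarray, y: np.ndarray, frac: float):
    """Fit lowess of y on x; return a callable predicting at new x values
    (flat extrapolation beyond the fitted range)."""
    fitted = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    xs, idx = np.unique(xs, return_index=True)
    ys = ys[idx]
    return lambda xnew: np.interp(xnew, xs, ys)


# ---------------------------------------------------------------------------
# invariant-set selection and normalization


def select_invariant_set(
    arrays: Sequence[ArrayChannelData],
    cfg: NormConfig = NormConfig(),
) -> set[str]:
    """Iteratively select the rank-invariant gene set.

    Per-array channel intensities are reconstructed as ch1 = A + M/2 and
    ch2 = A - M/2 and ranked jointly: a gene is a candidate when, on
    *every* array, the two channel values occupy nearly the same quantile
    of the pooled two-channel intensity distribution (pooled-rank
    difference below the configured threshold fraction).  Ranking both
    channels against the same pooled distribution makes the criterion a
    per-gene one -- it stays valid when the majority of genes shift,
    which would drag apart the within-channel ranks of genuinely
    unchanged genes.  After each selection the per-array M values are
    re-centred by the lowess trend fitted on the current candidate set
    and selection repeats, until the set changes by less than the
    convergence fraction or the iteration cap.  Re-centring only steers
    selection; callers normalize with :func:`invariant_normalize`
    afterwards.
    """
    arrays = list(arrays)
    if any(a.dye_swapped for a in arrays):
        logger.warning("selecting invariant genes on unoriented arrays; orient first")
    if any(a.A is None for a in arrays):
        raise ValueError("invariant selection needs A values on every array")
    genes = arrays[0].genes
    G = len(genes)
    M = np.column_stack([a.M for a in arrays])
    A = np.column_stack([a.A for a in arrays])
    prev: Optional[set[int]] = None
    current: set[int] = set()
    for _it in range(cfg.max_iterations):
        keep = np.ones(G, dtype=bool)
        for j in range(len(arrays)):
            ch1 = A[:, j] + M[:, j] / 2.0
            ch2 = A[:, j] - M[:, j] / 2.0
            pooled = sps.rankdata(np.concatenate([ch1, ch2]))
            r1, r2 = pooled[:G], pooled[G:]
            keep &= np.abs(r1 - r2) / (2 * G) < cfg.rank_diff_threshold
            # rank separation loses resolution in the sparse intensity
            # tails; an absolute cap on the (re-centred) log-ratio keeps
            # strongly changed tail genes out of the anchor set
            keep &= np.abs(M[:, j]) < cfg.max_abs_m
        current = set(np.nonzero(keep)[0])
        if not current:
            raise ValueError(
                "invariant set is empty; increase rank_diff_threshold"
            )
        if prev is not None:
            change = len(current.symmetric_difference(prev)) / len(current)
            if change < cfg.convergence:
                break
        prev = current
        sel = np.fromiter(sorted(current), dtype=int)
        for j in range(len(arrays)):
            curve = _lowess_curve(A[sel, j], M[sel, j], cfg.smoother_span)
            M[:, j] = M[:, j] - curve(A[:, j])
    return {str(g) for g in genes[np.fromiter(sorted(current), dtype=int)]}


def invariant_normalize(
    arrays: Sequence[ArrayChannelData],
    invariant_set: set[str],
    cfg: NormConfig = NormConfig(),
) -> list[ArrayChannelData]:
    """Subtract, per array, the lowess trend of M on A fitted over the
    invariant genes only; afterwards the invariant genes' median M is
    removed so it sits at ~0."""
    if not invariant_set:
        raise ValueError("invariant set is empty")
    out = []
    for a in arrays:
        if a.A is None:
            raise ValueError(f"array {a.array_id} has no A values")
        mask = np.isin(a.genes.astype(str), list(invariant_set))
        n_inv = int(mask.sum())
        if n_inv < cfg.min_invariant:
            raise ValueError(
                f"only {n_inv} invariant genes on array {a.array_id}; "
                f"need >= {cfg.min_invariant} for a reliable curve"
            )
        curve = _lowess_curve(a.A[mask], a.M[mask], cfg.smoother_span)
        m = a.M - curve(a.A)
        m = m - np.nanmedian(m[mask])
        out.append(replace(a, M=m))
    return out


def median_center(arrays: Sequence[ArrayChannelData]) -> list[ArrayChannelData]:
    """Global median-centring control: subtract each array's median M.

    Biased whenever the typical gene changes expression; provided for
    comparison with the invariant-set pipeline.
    """
    return [replace(a, M=a.M - np.nanmedian(a.M)) for a in arrays]


def normalize_expression(
    arrays: Sequence[ArrayChannelData],
    cfg: NormConfig = NormConfig(),
) -> tuple[list[ArrayChannelData], set[str]]:
    """Orient dye swaps, select the invariant set, normalize. Returns
    (normalized arrays, invariant gene set)."""
    oriented = orient_dye_swaps(arrays)
    inv = select_invariant_set(oriented, cfg)
    return invariant_normalize(oriented, inv, cfg), inv


# ---------------------------------------------------------------------------
# differential-expression calls


def call_de(
    arrays: Sequence[ArrayChannelData],
    m_threshold: float = 1.0,
    p_threshold: float = 0.01,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Per-gene one-sample t-test of oriented, normalized M against 0.

    A gene is "up" when aveM >= m_threshold and p < p_threshold, "down"
    symmetrically, otherwise "unchanged".  Genes with fewer than
    ``min_obs`` non-missing replicates are reported "untested" (p = NaN).
    Zero-variance genes get p = 1 when aveM = 0, else p = 0 (with a
    warning): the observed replicates are all identical.

    Returns a DataFrame with columns gene_id, aveM, p_value, n_obs, call.
    """
    arrays = list(arrays)
    if any(a.dye_swapped for a in arrays):
        logger.warning("calling DE on unoriented arrays; orient first")
    genes = arrays[0].genes.astype(str)
    M = np.column_stack([a.M for a in arrays])
    n_obs = np.sum(~np.isnan(M), axis=1)
    with np.errstate(invalid="ignore"):
        ave = np.nanmean(np.where(np.isnan(M), np.nan, M), axis=1)
        sd = np.nanstd(M, axis=1, ddof=1)
    p = np.full(len(genes), np.nan)
    tested = n_obs >= min_obs
    zero_var = tested & (sd == 0)
    ok = tested & (sd > 0)
    se = sd[ok] / np.sqrt(n_obs[ok])
    t = ave[ok] / se
    p[ok] = 2.0 * sps.t.sf(np.abs(t), df=n_obs[ok] - 1)
    if zero_var.any():
        p[zero_var] = np.where(ave[zero_var] == 0.0, 1.0, 0.0)
        if np.any(ave[zero_var] != 0.0):
            logger.warning(
                "%d genes with zero replicate variance and non-zero aveM (p set to 0)",
                int(np.sum(ave[zero_var] != 0.0)),
            )
    call = np.where(
        tested & (p < p_threshold) & (ave >= m_threshold),
        "up",
        np.where(tested & (p < p_threshold) & (ave <= -m_threshold), "down", "unchanged"),
    )
    call = np.where(tested, call, "untested")
    return pd.DataFrame(
        {
            "gene_id": genes,
            "aveM": ave,
            "p_value": p,
            "n_obs": n_obs,
            "call": call,
        }
    )


# ---------------------------------------------------------------------------
# I/O: TSV with M.<array> / A.<array> columns; a '#swapped=' comment line
# flags dye-swapped arrays


def write_expression_tsv(arrays: Sequence[ArrayChannelData], path: str | Path) -> None:
    genes = arrays[0].genes.astype(str)
    df = pd.DataFrame({"gene_id": genes})
    for a in arrays:
        df[f"M.{a.array_id}"] = a.M
        if a.A is not None:
            df[f"A.{a.array_id}"] = a.A
    swapped = [a.array_id for a in arrays if a.dye_swapped]
    with open(path, "w") as fh:
        fh.write("#swapped=" + ",".join(swapped) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> list[ArrayChannelData]:
    swapped: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#swapped="):
            names = first.strip().split("=", 1)[1]
            swapped = {n for n in names.split(",") if n}
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", comment="#")
    genes = df["gene_id"].astype(str).to_numpy()
    arrays = []
    for col in df.columns:
        if col.startswith("M."):
            aid = col[2:]
            A = df[f"A.{aid}"].to_numpy() if f"A.{aid}" in df.columns else None
            arrays.append(
                ArrayChannelData(
                    array_id=aid,
                    genes=genes,
                    M=df[col].to_numpy(),
                    A=A,
                    dye_swapped=aid in swapped,
                )
            )
    if not arrays:
        raise ValueError(f"no 'M.<array>' columns found in {path}")
    return arrays
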