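"""SAM-style two-class unpaired permutation testing with fold-change gating.

The moderated difference statistic is

    d_i = (mean_a_i - mean_b_i) / (s_i + s0)

with ``s_i`` the pooled two-sample standard error of gene *i* on the log2
scale and ``s0`` a small positive constant (the "fudge factor") chosen from
the distribution of the ``s_i`` to stabilise low-variance genes.  Setting
``s0 = 0`` recovers the equal-variance two-sample t statistic exactly.

Significance is assessed against the permutation distribution of *d* over
two-class label reassignments.  With small replicate numbers the complete
set of C(n, n_a) assignments is enumerated (20 for a 3-vs-3 design);
otherwise assignments are sampled with a seeded generator, always
including the identity so p-values are strictly positive.  Ties
|d*| == |d| count as exceedances (conservative).

Two p-value conventions are offered:

``across_genes`` (default)
    The permuted statistics of *all* genes form one pooled null
    distribution and each gene's p is the pooled tail fraction at its
    observed |d|.  This is the convention of the original SAM software and
    is the only one that can resolve p below 1/#assignments — necessary
    when only 20 assignments exist but a 0.05 cutoff is applied.

``per_gene``
    Each gene is compared only against its own permuted statistics; p is a
    multiple of 1/#assignments.  Note that the label-swap (complement)
    assignment always reproduces |d| exactly, so per-gene p can never fall
    below 2/#assignments.

A gene is called differentially expressed only when the permutation p is
below ``p_threshold`` *and* the linear fold change clears ``fc_threshold``
in either direction — the conjunction rule.

False-discovery q-values are estimated SAM-style: at each observed |d|
cutoff, the median across permutations of the number of permuted
statistics exceeding the cutoff, divided by the number of observed calls,
clipped to [0, 1] and monotonised.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import COLD_TIMEPOINTS, ExpressionMatrix, FormatError


class ContractError(ValueError):
    """Raised when inputs violate a statistical-contract precondition."""


@dataclass
class SamParams:
    n_permutations: int = 1000
    s0_mode: str = "percentile"  # or "fixed"
    s0_value: float = 50.0  # percentile of the s_i distribution, or fixed s0
    seed: int = 0
    fc_threshold: float = 5.0
    p_threshold: float = 0.05
    pooling: str = "across_genes"  # or "per_gene"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ContractError("fc_threshold must be > 1")
        if not (0 < self.p_threshold <= 1):
            raise ContractError("p_threshold must be in (0, 1]")
        if self.s0_mode not in ("percentile", "fixed"):
            raise ContractError(f"unknown s0_mode {self.s0_mode!r}")
        if self.pooling not in ("across_genes", "per_gene"):
            raise ContractError(f"unknown pooling {self.pooling!r}")
        if self.n_permutations < 2:
            raise ContractError("need n_permutations >= 2")


# ----------------------------------------------------------------------
# the statistic


def _pooled_se_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled two-sample standard error, rows = genes."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return np.sqrt(sp2 * (1.0 / na + 1.0 / nb))


def sam_d(values_a, values_b, s0: float) -> tuple[float, float, float, float]:
    """d, mean_a, mean_b and pooled SE for one gene.

    Requires >= 2 values per group.  Antisymmetric under group swap.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ContractError("sam_d needs two 1-D groups with >= 2 values each")
    se = float(_pooled_se_arrays(a[None, :], b[None, :])[0])
    mean_a, mean_b = float(a.mean()), float(b.mean())
    denom = se + s0
    if denom == 0:
        d = 0.0 if mean_a == mean_b else math.copysign(math.inf, mean_a - mean_b)
    else:
        d = (mean_a - mean_b) / denom
    return d, mean_a, mean_b, se


def choose_s0(pooled_ses, mode: str = "percentile", value: float = 50.0) -> float:
    """Fudge factor from the distribution of per-gene pooled SEs."""
    ses = np.asarray(pooled_ses, dtype=float)
    if ses.size == 0:
        raise ContractError("choose_s0 needs a non-empty SE collection")
    if mode == "fixed":
        return float(value)
    if mode == "percentile":
        return float(np.percentile(ses, value))
    raise ContractError(f"unknown s0 mode {mode!r}")


# ----------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationResult:
    d: np.ndarray
    pooled_se: np.ndarray
    s0: float
    p: np.ndarray
    q: np.ndarray
    n_assignments: int
    exhaustive: bool


def _enumerate_assignments(n: int, n_a: int, params: SamParams) -> tuple[list[tuple[int, ...]], bool]:
    total = math.comb(n, n_a)
    if total < 2:
        raise ContractError(
            f"only {total} distinct label assignment(s) exist for {n_a} of {n} samples; "
            "a permutation test is infeasible"
        )
    identity = tuple(range(n_a))
    if total <= params.n_permutations:
        return [tuple(c) for c in itertools.combinations(range(n), n_a)], True
    rng = np.random.default_rng(params.seed)
    assignments = [identity]
    for _ in range(params.n_permutations - 1):
        assignments.append(tuple(sorted(rng.choice(n, size=n_a, replace=False).tolist())))
    return assignments, False


def _d_matrix(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float) -> np.ndarray:
    means = X[:, idx_a].mean(axis=1) - X[:, idx_b].mean(axis=1)
    se = _pooled_se_arrays(X[:, idx_a], X[:, idx_b])
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = means / denom
    d[np.isnan(d)] = 0.0  # 0/0: identical constant groups
    return d


def permutation_test(X, n_a: int, params: SamParams) -> PermutationResult:
    """Permutation p and q values for a genes x samples log2 slice.

    ``X`` has the ``n_a`` group-A columns first, group B after.  Observed
    statistics correspond to the identity assignment, which is always part
    of the enumerated/sampled assignment set.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ContractError("permutation_test expects a 2-D genes x samples array")
    n = X.shape[1]
    n_b = n - n_a
    if n_a < 2 or n_b < 2:
        raise ContractError("need >= 2 samples per group")
    all_idx = np.arange(n)

    se_obs = _pooled_se_arrays(X[:, :n_a], X[:, n_a:])
    s0 = choose_s0(se_obs, params.s0_mode, params.s0_value)

    assignments, exhaustive = _enumerate_assignments(n, n_a, params)
    B = len(assignments)
    G = X.shape[0]
    D = np.empty((G, B))
    for b, idx in enumerate(assignments):
        ia = np.asarray(idx)
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        D[:, b] = _d_matrix(X, ia, ib, s0)
    identity = tuple(range(n_a))
    obs_col = assignments.index(identity)
    d_obs = D[:, obs_col]
    absD = np.abs(D)
    t = np.abs(d_obs)

    if params.pooling == "across_genes":
        pool = np.sort(absD.ravel())
        exceed = pool.size - np.searchsorted(pool, t, side="left")
        p = exceed / pool.size
    else:
        p = (absD >= t[:, None]).sum(axis=1) / B

    q = _sam_q(absD, t)
    return PermutationResult(
        d=d_obs, pooled_se=se_obs, s0=s0, p=p, q=q, n_assignments=B, exhaustive=exhaustive
    )


def _sam_q(absD: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Median-false-call FDR estimate at each gene's |d| cutoff."""
    G, B = absD.shape
    order = np.argsort(-thresholds, kind="stable")
    t_sorted = thresholds[order]
    # per permutation: count of |d*| >= each threshold
    false_counts = np.empty((B, G))
    for b in range(B):
        col = np.sort(absD[:, b])
        false_counts[b] = G - np.searchsorted(col, t_sorted, side="left")
    med_false = np.median(false_counts, axis=0)
    called = np.arange(1, G + 1)  # t_sorted is descending: rank = calls at cutoff
    q_sorted = np.clip(med_false / called, 0.0, 1.0)
    # monotone: a larger |d| cutoff never has a larger q
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(G)
    q[order] = q_sorted
    return q


# ----------------------------------------------------------------------
# contrasts and DEG calling


@dataclass(frozen=True)
class Contrast:
    """A resolvable two-group comparison in the time-course design.

    ``cold_vs_control``: cold samples of one genotype at one timepoint vs
    that genotype's pooled control.  ``il_vs_recurrent``: the two genotypes
    at one condition/timepoint (``time_h=0`` means control).
    """

    kind: str  # "cold_vs_control" | "il_vs_recurrent"
    genotype: str | None = None
    time_h: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cold_vs_control", "il_vs_recurrent"):
            raise ContractError(f"unknown contrast kind {self.kind!r}")
        if self.kind == "cold_vs_control":
            if self.genotype is None or self.time_h <= 0:
                raise ContractError("cold_vs_control needs a genotype and a positive timepoint")

    @property
    def label(self) -> str:
        if self.kind == "cold_vs_control":
            return f"{self.genotype}-cold-{self.time_h}h-vs-control"
        at = "control" if self.time_h == 0 else f"{self.time_h}h"
        return f"introgression-vs-recurrent-at-{at}"

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse CLI syntax: ``<genotype>:cold@<T>h:vs:control`` or
        ``il_vs_recurrent@<T>h`` / ``il_vs_recurrent@control``."""
        text = text.strip()
        if text.startswith("il_vs_recurrent@"):
            at = text.split("@", 1)[1]
            t = 0 if at == "control" else int(at.rstrip("h"))
            return cls("il_vs_recurrent", None, t)
        parts = text.split(":")
        if len(parts) == 4 and parts[2] == "vs" and parts[3] == "control":
            genotype = parts[0]
            cond, at = parts[1].split("@")
            if cond != "cold":
                raise ContractError(f"cannot parse contrast {text!r}")
            return cls("cold_vs_control", genotype, int(at.rstrip("h")))
        raise ContractError(f"cannot parse contrast {text!r}")

    def groups(self, matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
        if self.kind == "cold_vs_control":
            a = matrix.select(genotype=self.genotype, condition="cold", time_h=self.time_h)
            b = matrix.select(genotype=self.genotype, condition="control")
        else:
            cond = "control" if self.time_h == 0 else "cold"
            a = matrix.select(genotype="introgression", condition=cond, time_h=self.time_h)
            b = matrix.select(genotype="recurrent", condition=cond, time_h=self.time_h)
        if not a or not b:
            raise ContractError(f"contrast {self.label!r} not resolvable from the design")
        return a, b


def all_contrasts(timepoints=COLD_TIMEPOINTS) -> list[Contrast]:
    """Every within-genotype cold contrast plus the genotype contrast at
    control and at each timepoint."""
    out: list[Contrast] = []
    for genotype in ("recurrent", "introgression"):
        for t in timepoints:
            out.append(Contrast("cold_vs_control", genotype, t))
    out.append(Contrast("il_vs_recurrent", None, 0))
    for t in timepoints:
        out.append(Contrast("il_vs_recurrent", None, t))
    return out


DEG_COLUMNS = [
    "gene_id",
    "contrast",
    "mean_a",
    "mean_b",
    "pooled_se",
    "d_statistic",
    "fold_change",
    "p_value",
    "q_value",
    "direction",
    "significant",
]


def call_degs(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    params: SamParams | None = None,
    expressed: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One DEG record per (expressed) gene for the given contrast.

    The d statistic and permutation p are computed on log2(value +
    pseudocount); the fold change is the ratio of linear group means.
    Significance is the conjunction of the p cutoff and the fold-change
    gate in either direction.
    """
    if params is None:
        params = SamParams()
    if matrix.scale != "linear":
        raise FormatError("call_degs expects a linear-scale (normalized) matrix")
    work = matrix if expressed is None else matrix.subset_genes(expressed)
    ids_a, ids_b = contrast.groups(work)
    lin = work.values
    mean_a = lin[ids_a].mean(axis=1)
    mean_b = lin[ids_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (mean_a / mean_b).replace(np.nan, 1.0)

    log2 = np.log2(lin[ids_a + ids_b].to_numpy() + pseudocount)
    res = permutation_test(log2, n_a=len(ids_a), params=params)

    sig = (res.p < params.p_threshold) & (
        (fc > params.fc_threshold) | (fc < 1.0 / params.fc_threshold)
    )
    out = pd.DataFrame(
        {
            "gene_id": work.gene_ids,
            "contrast": contrast.label,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "pooled_se": res.pooled_se,
            "d_statistic": res.d,
            "fold_change": fc.to_numpy(),
            "p_value": res.p,
            "q_value": res.q,
            "direction": np.where(fc.to_numpy() > 1.0, "induced", "repressed"),
            "significant": sig.to_numpy(),
        }
    )
    return out
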