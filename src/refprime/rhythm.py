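"""JTK-style rhythmicity detection.

Flags rhythmically regulated genes by Kendall concordance of the observed
series against a family of phase-shifted cosine reference waveforms, the
construction of the Jonckheere-Terpstra-Kendall (JTK) cycle family of tests.
Replicates at a time point share the reference value (tied reference ranks).

The null distribution of the Kendall S statistic against a fixed, possibly
tied reference is the Jonckheere-Terpstra null over the reference tie
groups; for tie-free observations it is computed exactly at any series
length by convolution of Mann-Whitney count distributions.  Observations
with ties fall back to a seeded Monte-Carlo permutation null.  Per gene the
minimum p over the reference family is Bonferroni-multiplied by the family
size and capped at 1; across genes, q-values are Benjamini-Hochberg.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from statsmodels.stats.multitest import multipletests

from .expression import SampleMeta, TimeCourseMatrix

__all__ = [
    "RhythmResult",
    "kendall_tau_s",
    "jtk_test",
    "jtk_scan",
    "bh_adjust",
    "import_rhythm_calls",
    "exact_s_null",
]

DEFAULT_PERIODS = (22.0,)  # hours; the Neurospora circadian regime
DEFAULT_ALPHA = 0.05


@dataclass
class RhythmResult:
    gene_id: str
    p_value: float | None
    q_value: float
    best_period: float | None = None
    best_phase: float | None = None
    is_rhythmic: bool = False


def kendall_tau_s(x: Sequence[float], ref: Sequence[float]) -> tuple[float, int]:
    """Kendall concordance of ``x`` against ``ref``.

    Returns ``(tau, S)`` where ``S = sum over pairs i<j of
    sign((x_j - x_i) * (ref_j - ref_i))`` and tau is tau-b (tie-corrected).
    An all-tied ``x`` has tau defined as 0.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {ref.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = np.sign(x[None, :] - x[:, None])
    dref = np.sign(ref[None, :] - ref[:, None])
    s = int(np.sum(np.triu(dx * dref, k=1)))
    tau = kendalltau(x, ref).statistic
    if not np.isfinite(tau):
        tau = 0.0
    return float(tau), s


# ---------------------------------------------------------------------------
# exact null of S by Jonckheere-Terpstra convolution
# ---------------------------------------------------------------------------


def _mw_counts_dp(m: int, n: int) -> np.ndarray:
    """Mann-Whitney U count distribution for group sizes (m, n).

    ``out[u]`` = number of interleavings of m+n distinct values with exactly
    u (first-group, second-group) pairs in ascending order; u in 0..m*n.

    Recurrence on the overall maximum: if it belongs to the second group it
    contributes m pairs (f[m][n-1] shifted by m), else none (f[m-1][n]).
    """
    size = m * n + 1
    # table[i] = count array for group sizes (i, current n column)
    table = [np.zeros(size) for _ in range(m + 1)]
    for i in range(m + 1):
        table[i][0] = 1.0  # n = 0
    for _ in range(1, n + 1):
        new = [np.zeros(size) for _ in range(m + 1)]
        new[0][0] = 1.0
        for i in range(1, m + 1):
            shifted = np.zeros(size)
            shifted[i:] = table[i][: size - i]
            new[i] = shifted + new[i - 1]
        table = new
    return table[m]


@functools.lru_cache(maxsize=512)
def exact_s_null(group_sizes: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Exact null pmf of the Kendall S statistic against a tied reference.

    ``group_sizes`` are the sizes of the reference tie groups (ordered by
    reference value; the order does not affect the null).  Valid when the
    observed values are tie-free.  Returns ``(pmf over U = 0..U_max, U_max)``
    with ``S = 2*U - U_max``.

    The Jonckheere-Terpstra statistic over sequentially added groups is the
    sum of independent Mann-Whitney statistics, so its pmf is their
    convolution.
    """
    sizes = [s for s in group_sizes if s > 0]
    u_max = 0
    pmf = np.array([1.0])
    cum = 0
    for s in sizes:
        if cum > 0:
            counts = _mw_counts_dp(cum, s)
            counts /= counts.sum()
            pmf = np.convolve(pmf, counts)
            u_max += cum * s
        cum += s
    return pmf, u_max


def _p_two_sided_exact(s_obs: int, group_sizes: tuple[int, ...]) -> float:
    pmf, u_max = exact_s_null(group_sizes)
    # S values for U=0..U_max are 2U - U_max
    s_vals = 2 * np.arange(u_max + 1) - u_max
    return float(pmf[np.abs(s_vals) >= abs(s_obs)].sum())


@functools.lru_cache(maxsize=64)
def _p_lookup(group_sizes: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Two-sided exact p indexed by U = (S + U_max) / 2, plus U_max."""
    pmf, u_max = exact_s_null(group_sizes)
    s_vals = 2 * np.arange(u_max + 1) - u_max
    p = np.array([pmf[np.abs(s_vals) >= abs(s)].sum() for s in s_vals])
    return p, u_max


@functools.lru_cache(maxsize=16)
def _minp_family_null(
    times_key: tuple[float, ...],
    periods: tuple[float, ...],
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Sorted permutation null of min-p over the reference family.

    The joint law of the per-reference Kendall S statistics under random
    permutation of tie-free observations depends only on the reference
    family, so one seeded simulation per sampling design serves every gene:
    permute ranks, score S against every reference, convert each S to its
    exact two-sided p, and keep the minimum over references.
    """
    times = np.asarray(times_key)
    refs = cosine_references(times, periods)
    n = times.size
    rng = np.random.default_rng(seed)
    ranks = np.arange(n, dtype=float)
    tris = [np.triu(np.sign(r[None, :] - r[:, None]), k=1) for _, _, r in refs]
    lookups = [_p_lookup(_group_sizes(r)) for _, _, r in refs]
    minp = np.empty(n_perm)
    chunk = max(1, int(2e7 // (n * n)))  # bound the sign-tensor memory
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(ranks) for _ in range(k)])
        dperm = np.sign(perms[:, None, :] - perms[:, :, None]).astype(np.int8)
        mp = np.full(k, np.inf)
        for tri, (p_tab, u_max) in zip(tris, lookups):
            s = np.tensordot(dperm, tri, axes=([1, 2], [0, 1])).round().astype(int)
            mp = np.minimum(mp, p_tab[(s + u_max) // 2])
        minp[done : done + k] = mp
        done += k
    return np.sort(minp)


def _family_p(minp_obs: float, null_sorted: np.ndarray) -> float:
    k = int(np.searchsorted(null_sorted, minp_obs, side="right"))
    return (1.0 + k) / (null_sorted.size + 1.0)


# ---------------------------------------------------------------------------
# reference waveforms
# ---------------------------------------------------------------------------


def cosine_references(
    times: np.ndarray, periods: Sequence[float]
) -> list[tuple[float, float, np.ndarray]]:
    """Cosine reference values at each sample time.

    Phases lie on the sampling-interval grid (the minimal spacing of the
    distinct sample times), spanning one period.  Returns a list of
    ``(period, phase, ref_values)``.
    """
    times = np.asarray(times, dtype=float)
    distinct = np.unique(times)
    if distinct.size < 2:
        raise ValueError("need at least two distinct time points")
    interval = float(np.min(np.diff(distinct)))
    refs = []
    for period in periods:
        phases = np.arange(0.0, period, interval)
        for phase in phases:
            # quantize so that numerically near-equal cosine values form
            # genuine tie groups (sign structure must match the null's)
            ref = np.round(np.cos(2 * np.pi * (times - phase) / period), 9)
            refs.append((float(period), float(phase), ref))
    return refs


def _group_sizes(ref: np.ndarray) -> tuple[int, ...]:
    # references are pre-quantized, so exact equality defines the groups
    _, counts = np.unique(ref, return_counts=True)
    return tuple(int(c) for c in counts)


def jtk_test(
    gene_row: Sequence[float],
    meta: Sequence[SampleMeta],
    periods: Sequence[float] = DEFAULT_PERIODS,
    alpha: float = DEFAULT_ALPHA,
    *,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    correction: str = "permutation",
    gene_id: str = "",
) -> RhythmResult:
    """JTK-style rhythmicity test for one gene.

    For each candidate period and phase, the Kendall S of the observed values
    against the cosine reference is converted to an exact two-sided tail
    probability under the permutation null (Jonckheere-Terpstra convolution;
    Monte-Carlo when the observations themselves carry ties).  The minimum p
    over the reference family is then corrected for the family-wise search:
    ``correction="permutation"`` (default) calibrates min-p against its own
    seeded permutation null, which stays uniform under the null even though
    phase-shifted references are strongly correlated;
    ``correction="bonferroni"`` multiplies by the family size instead
    (conservative).  ``is_rhythmic`` here uses the unadjusted ``p < alpha``;
    across a gene set use :func:`jtk_scan` for BH-corrected calls.
    """
    x = np.asarray(gene_row, dtype=float)
    if x.size != len(meta):
        raise ValueError("gene_row and meta length mismatch")
    if x.size < 6:
        raise ValueError("need at least 6 samples for the rhythm test")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite expression values")
    if not periods:
        raise ValueError("periods must be non-empty")
    times = np.array([s.time for s in meta], dtype=float)
    refs = cosine_references(times, periods)

    x_tied = np.unique(x).size < x.size
    dperm: np.ndarray | None = None
    if x_tied:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        n_mc = min(n_perm, max(2000, int(4e8 // (x.size * x.size))))
        perm = np.stack([gen.permutation(x) for _ in range(n_mc)])
        dperm = np.sign(perm[:, None, :] - perm[:, :, None]).astype(np.int8)

    dx = np.sign(x[None, :] - x[:, None])
    best = None
    for period, phase, ref in refs:
        dref = np.sign(ref[None, :] - ref[:, None])
        s_obs = int(np.sum(np.triu(dx * dref, k=1)))
        if x_tied:
            assert dperm is not None
            tri = np.triu(dref, k=1)
            s_perm = np.tensordot(dperm, tri, axes=([1, 2], [0, 1]))
            p = (1.0 + np.sum(np.abs(s_perm) >= abs(s_obs))) / (s_perm.size + 1.0)
        else:
            p = _p_two_sided_exact(s_obs, _group_sizes(ref))
        if best is None or p < best[0]:
            best = (p, period, phase)
    assert best is not None
    if correction == "permutation" and not x_tied:
        seed = rng if isinstance(rng, int) else 0
        null = _minp_family_null(tuple(times.tolist()), tuple(periods), n_perm, seed)
        p_adj = _family_p(best[0], null)
    else:
        p_adj = min(1.0, best[0] * len(refs))
    return RhythmResult(
        gene_id=gene_id,
        p_value=p_adj,
        q_value=p_adj,  # caller overrides after BH across genes
        best_period=best[1],
        best_phase=best[2],
        is_rhythmic=p_adj < alpha,
    )


def jtk_scan(
    m: TimeCourseMatrix,
    periods: Sequence[float] = DEFAULT_PERIODS,
    alpha: float = DEFAULT_ALPHA,
    *,
    rng: np.random.Generator | int | None = None,
    correction: str = "permutation",
    n_perm: int = 10000,
) -> list[RhythmResult]:
    """Run :func:`jtk_test` on every gene and BH-adjust across the gene set.

    Vectorized over genes; references, exact nulls, and the min-p
    permutation null are shared across the whole matrix.
    """
    times = m.times
    refs = cosine_references(times, periods)
    drefs = np.stack(
        [np.triu(np.sign(r[None, :] - r[:, None]), k=1) for _, _, r in refs]
    )  # (R, n, n)
    n_refs = len(refs)
    lookups = [_p_lookup(_group_sizes(r)) for _, _, r in refs]
    p_raw = np.empty(m.n_genes)
    tied = np.zeros(m.n_genes, dtype=bool)
    best_idx = np.empty(m.n_genes, dtype=int)
    seed = rng if isinstance(rng, int) else 0
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for i in range(m.n_genes):
        x = m.values[i]
        if np.unique(x).size < x.size:
            res = jtk_test(
                x, m.samples, periods, alpha,
                rng=gen, correction="bonferroni", gene_id=m.gene_ids[i],
            )
            p_raw[i] = res.p_value if res.p_value is not None else 1.0
            tied[i] = True
            best_idx[i] = next(
                k for k, (pp, ph, _) in enumerate(refs)
                if pp == res.best_period and ph == res.best_phase
            )
            continue
        dx = np.sign(x[None, :] - x[:, None])
        s_all = np.tensordot(drefs, dx, axes=([1, 2], [0, 1])).round().astype(int)
        ps = np.array(
            [lookups[k][0][(s + lookups[k][1]) // 2] for k, s in enumerate(s_all)]
        )
        best_idx[i] = int(np.argmin(ps))
        p_raw[i] = ps[best_idx[i]]
    p_adj = np.empty_like(p_raw)
    p_adj[tied] = p_raw[tied]  # already family-corrected (Bonferroni)
    free = ~tied
    if np.any(free):
        if correction == "permutation":
            null = _minp_family_null(tuple(times.tolist()), tuple(periods), n_perm, seed)
            ranks = np.searchsorted(null, p_raw[free], side="right")
            p_adj[free] = (1.0 + ranks) / (null.size + 1.0)
        else:
            p_adj[free] = np.minimum(1.0, p_raw[free] * n_refs)
    q = bh_adjust(p_adj.tolist())
    out = []
    for i, gene in enumerate(m.gene_ids):
        period, phase, _ = refs[best_idx[i]]
        out.append(
            RhythmResult(
                gene_id=gene,
                p_value=float(p_adj[i]),
                q_value=float(q[i]),
                best_period=period,
                best_phase=phase,
                is_rhythmic=q[i] < alpha,
            )
        )
    return out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def import_rhythm_calls(path: Path | str, alpha: float = DEFAULT_ALPHA) -> list[RhythmResult]:
    """Load precomputed rhythmicity calls (TSV with gene_id and q_value).

    A p_value column is carried through if present.  ``is_rhythmic`` is the
    strict ``q < alpha``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "q_value"):
        if col not in df.columns:
            raise ValueError(f"rhythm-call file missing column {col!r}")
    has_p = "p_value" in df.columns
    out = []
    for r in df.itertuples():
        q = float(r.q_value)
        out.append(
            RhythmResult(
                gene_id=str(r.gene_id),
                p_value=float(r.p_value) if has_p else None,
                q_value=q,
                is_rhythmic=q < alpha,
            )
        )
    return out
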