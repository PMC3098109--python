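"""Linkage-disequilibrium statistics over SNP sets.

A multi-marker tagging rule S → SNP_x treats the haplotypes over the SNP
set S as the "alleles" of a derived marker: the observed haplotypes are
split into two groups, the groups are mapped to the two alleles A (major)
and a (minor) of SNP_x, and the ordinary r² statistic is computed between
the derived bi-allelic marker and SNP_x:

    r² = (P(H_A A) − P(H_A) P(A))² / (P(H_A) P(H_a) P(A) P(a))

Two grouping models are implemented.  The *co-occurrence* model maps each
haplotype H to the allele it co-occurs with more often (f(HA) > f(Ha) → A,
otherwise a).  The *one-vs-the-rest* model tries every grouping that
isolates a single observed haplotype against all others and keeps the one
with the highest r².  At |S| = 1 both reduce to the ordinary pairwise r².

All frequencies are relative frequencies over haplotypes (rows); no
small-sample correction is applied.  The *_from_counts helpers are the
single source of every r² value: rule enumeration feeds them precomputed
joint counts, so thresholds and stored r² agree bit for bit with the
public functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import HaplotypePanel

COOCCURRENCE = "cooccurrence"
ONE_VS_REST = "one_vs_rest"
MODELS = (COOCCURRENCE, ONE_VS_REST)


@dataclass(frozen=True)
class HaplotypeDistribution:
    """Exact multinomial counts of the observed haplotypes over a SNP set."""

    snp_set: tuple[int, ...]
    counts: dict[tuple[int, ...], int]
    total: int


@dataclass(frozen=True)
class GroupedMarker:
    """A grouping of observed LHS haplotypes into the two pseudo-alleles.

    ``group_A`` holds the haplotype keys mapped to the RHS major allele,
    ``group_a`` those mapped to the minor allele.  The p_* fields are the
    relative frequencies entering the r² formula.
    """

    group_A: frozenset
    group_a: frozenset
    p_HA: float
    p_Ha: float
    p_A: float
    p_a: float
    p_HA_and_A: float


@dataclass(frozen=True)
class R2Result:
    r2: float
    grouping: GroupedMarker | None
    defined: bool = True


def haplotype_frequencies(
    panel: HaplotypePanel, snp_set: list[int] | tuple[int, ...]
) -> HaplotypeDistribution:
    """Count the observed haplotypes of the given SNP columns."""
    snp_set = tuple(snp_set)
    if not snp_set:
        raise ValueError("empty snp_set")
    if len(set(snp_set)) != len(snp_set):
        raise ValueError("snp_set indices must be distinct")
    sub = panel.matrix[:, snp_set]
    keys, counts = np.unique(sub, axis=0, return_counts=True)
    return HaplotypeDistribution(
        snp_set,
        {tuple(int(v) for v in k): int(c) for k, c in zip(keys, counts)},
        panel.n_haplotypes,
    )


def _eq1_counts(n: int, c_HA: int, c_A: int, c_HAA: int) -> float:
    """The r² of a fixed grouping, from integer counts.

    All frequencies are multiples of 1/n, so the covariance and variances
    are exact integers after clearing denominators:

        r² = (n·c_HAA − c_HA·c_A)² / (c_HA·(n−c_HA)·c_A·(n−c_A))

    This keeps perfect LD at exactly 1.0 and guarantees r² ∈ [0, 1]
    (Cauchy-Schwarz holds in exact integer arithmetic).  Shared by training
    and test evaluation so self-evaluation reproduces stored values.
    """
    denom = c_HA * (n - c_HA) * c_A * (n - c_A)
    if denom == 0:
        return 0.0
    num = n * c_HAA - c_HA * c_A
    return (num * num) / denom


def key_codes(panel: HaplotypePanel, S: tuple[int, ...]) -> np.ndarray:
    """Per-haplotype integer encoding of the alleles over S (first SNP is
    the most significant bit)."""
    codes = np.zeros(panel.n_haplotypes, dtype=np.int64)
    for s in S:
        codes = codes * 2 + panel.matrix[:, s]
    return codes


def joint_counts(panel: HaplotypePanel, S: tuple[int, ...], x: int):
    """(nA, na): for each of the 2^k LHS haplotype codes, its count of
    co-occurrences with the RHS major (code 0) and minor (code 1) allele."""
    k = len(S)
    joint = key_codes(panel, S) * 2 + panel.matrix[:, x]
    counts = np.bincount(joint, minlength=2 ** (k + 1))
    return counts[0::2], counts[1::2]


def pairwise_r2_from_counts(nA: np.ndarray, na: np.ndarray) -> float:
    """Ordinary pairwise r² from length-2 joint counts (k = 1)."""
    n = int(nA.sum() + na.sum())
    c_i = int((nA + na)[0])  # lhs major-allele count
    c_A = int(nA.sum())
    return _eq1_counts(n, c_i, c_A, int(nA[0]))


def cooccurrence_r2_from_counts(nA: np.ndarray, na: np.ndarray) -> float:
    """Co-occurrence-model r² from joint counts (0.0 when the majority
    mapping leaves one group empty).  Single-SNP rules (length-2 count
    vectors) are the pairwise model and use the ordinary r² formula."""
    if len(nA) == 2:
        return pairwise_r2_from_counts(nA, na)
    n = int(nA.sum() + na.sum())
    tot = nA + na
    observed = tot > 0
    group_A = nA > na
    group_a = observed & ~group_A
    if not group_A.any() or not group_a.any():
        return 0.0
    c_A = int(nA.sum())
    c_HA = int(tot[group_A].sum())
    c_HAA = int(nA[group_A].sum())
    return _eq1_counts(n, c_HA, c_A, c_HAA)


def one_vs_rest_r2_from_counts(nA: np.ndarray, na: np.ndarray) -> tuple[float, int]:
    """Best one-vs-the-rest r² from joint counts.

    Returns (r², code of the isolated haplotype; -1 when fewer than two
    haplotypes are observed).  Flipping which group maps to which allele
    negates the covariance and leaves r² unchanged, so only the partition
    matters here.  Single-SNP rules are the pairwise model.
    """
    if len(nA) == 2:
        r2 = pairwise_r2_from_counts(nA, na)
        best = 0 if (nA + na)[0] > 0 else -1
        return r2, best
    n = int(nA.sum() + na.sum())
    tot = nA + na
    observed = tot > 0
    if int(observed.sum()) < 2:
        return 0.0, -1
    c_A = int(nA.sum())
    if c_A in (0, n):
        return 0.0, -1
    best_r2, best = 0.0, -1
    for code in np.nonzero(observed)[0]:
        c_G = int(tot[code])
        if c_G == n:
            continue
        r2 = _eq1_counts(n, c_G, c_A, int(nA[code]))
        if best < 0 or r2 > best_r2:
            best_r2, best = r2, int(code)
    return best_r2, best


def _pairwise_r2_many(counts: np.ndarray) -> np.ndarray:
    nA = counts[:, :, 0]
    na = counts[:, :, 1]
    tot = nA + na
    n = int(tot[0].sum())
    c_i = tot[:, 0]
    c_A = nA.sum(axis=1)
    num = n * nA[:, 0] - c_i * c_A
    denom = c_i * (n - c_i) * c_A * (n - c_A)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (num * num) / denom
    return np.where(denom != 0, r2, 0.0)


def cooccurrence_r2_many(counts: np.ndarray) -> np.ndarray:
    """Vectorized co-occurrence r² for many targets at once.

    ``counts`` has shape (m, 2^k, 2): joint counts per target SNP, LHS
    haplotype code, RHS allele.  Identical integer arithmetic (hence
    identical floats) to :func:`cooccurrence_r2_from_counts` per row.
    """
    if counts.shape[1] == 2:
        return _pairwise_r2_many(counts)
    nA = counts[:, :, 0]
    na = counts[:, :, 1]
    tot = nA + na
    n = int(tot[0].sum())
    observed = tot > 0
    group_A = nA > na
    group_a = observed & ~group_A
    ok = group_A.any(axis=1) & group_a.any(axis=1)
    c_A = nA.sum(axis=1)
    c_HA = np.where(group_A, tot, 0).sum(axis=1)
    c_HAA = np.where(group_A, nA, 0).sum(axis=1)
    num = n * c_HAA - c_HA * c_A
    denom = c_HA * (n - c_HA) * c_A * (n - c_A)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (num * num) / denom
    return np.where(ok & (denom != 0), r2, 0.0)


def one_vs_rest_r2_many(counts: np.ndarray) -> np.ndarray:
    """Vectorized one-vs-the-rest r² for many targets at once (shape as in
    :func:`cooccurrence_r2_many`)."""
    if counts.shape[1] == 2:
        return _pairwise_r2_many(counts)
    nA = counts[:, :, 0]
    na = counts[:, :, 1]
    tot = nA + na
    n = int(tot[0].sum())
    observed = tot > 0
    c_A = nA.sum(axis=1)
    c_G = tot
    num = n * nA - c_G * c_A[:, None]
    denom = c_G * (n - c_G) * (c_A * (n - c_A))[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (num * num) / denom
    r2 = np.where(observed & (denom != 0), r2, -1.0)
    best = r2.max(axis=1)
    ok = (observed.sum(axis=1) >= 2) & (c_A != 0) & (c_A != n)
    return np.where(ok, np.maximum(best, 0.0), 0.0)


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> R2Result:
    """Ordinary r² between two SNP columns; exactly symmetric in (i, j)."""
    if i == j:
        raise ValueError("i and j must differ")
    n = panel.n_haplotypes
    ci, cj = panel.matrix[:, i], panel.matrix[:, j]
    c_i = n - int(ci.sum())  # major-allele count at i
    c_j = n - int(cj.sum())
    if c_i in (0, n) or c_j in (0, n):
        return R2Result(float("nan"), None, defined=False)
    c_ij = int(np.sum((ci == 0) & (cj == 0)))
    r2 = _eq1_counts(n, c_i, c_j, c_ij)
    grouping = GroupedMarker(
        frozenset({(0,)}),
        frozenset({(1,)}),
        c_i / n,
        1.0 - c_i / n,
        c_j / n,
        1.0 - c_j / n,
        c_ij / n,
    )
    return R2Result(r2, grouping)


def _code_to_key(code: int, k: int) -> tuple[int, ...]:
    return tuple((code >> (k - 1 - b)) & 1 for b in range(k))


def _grouping_from_masks(
    nA: np.ndarray, na: np.ndarray, in_A: np.ndarray, k: int
) -> GroupedMarker:
    n = int(nA.sum() + na.sum())
    tot = nA + na
    observed = tot > 0
    group_A = frozenset(_code_to_key(c, k) for c in np.nonzero(observed & in_A)[0])
    group_a = frozenset(_code_to_key(c, k) for c in np.nonzero(observed & ~in_A)[0])
    p_A = int(nA.sum()) / n
    p_HA = int(tot[observed & in_A].sum()) / n
    p_HA_and_A = int(nA[observed & in_A].sum()) / n
    return GroupedMarker(
        group_A, group_a, p_HA, 1.0 - p_HA, p_A, 1.0 - p_A, p_HA_and_A
    )


def cooccurrence_r2(
    panel: HaplotypePanel, S: list[int] | tuple[int, ...], x: int
) -> R2Result:
    """r² of S → x under the majority-co-occurrence grouping.

    Each observed haplotype H maps to the major allele A when f(HA) > f(Ha)
    and to the minor allele a otherwise (ties included).  If every
    haplotype lands in one group no bi-allelic pseudo-marker exists and the
    result is r² = 0.
    """
    S = tuple(S)
    if x in S:
        raise ValueError("x must not be a member of S")
    cx = panel.matrix[:, x]
    if cx.min() == cx.max():
        return R2Result(float("nan"), None, defined=False)
    nA, na = joint_counts(panel, S, x)
    r2 = cooccurrence_r2_from_counts(nA, na)
    gm = _grouping_from_masks(nA, na, nA > na, len(S))
    return R2Result(r2, gm)


def one_vs_rest_r2(
    panel: HaplotypePanel, S: list[int] | tuple[int, ...], x: int
) -> R2Result:
    """Best r² of S → x over all groupings isolating one observed haplotype.

    Only observed haplotypes are tried (an unobserved one yields an empty
    group).  The returned grouping's allele orientation is chosen to
    maximise the number of correctly co-occurring haplotypes, which leaves
    the r² value unchanged but fixes the prediction mapping.
    """
    S = tuple(S)
    if x in S:
        raise ValueError("x must not be a member of S")
    cx = panel.matrix[:, x]
    if cx.min() == cx.max():
        return R2Result(float("nan"), None, defined=False)
    nA, na = joint_counts(panel, S, x)
    r2, best = one_vs_rest_r2_from_counts(nA, na)
    k = len(S)
    if best < 0:
        observed = (nA + na) > 0
        gm = _grouping_from_masks(nA, na, observed, k)
        return R2Result(0.0, gm)
    # orientation of the prediction mapping: put the isolated haplotype on
    # the allele side it predicts best
    totA, tota = int(nA.sum()), int(na.sum())
    correct_to_A = int(nA[best]) + (tota - int(na[best]))
    correct_to_a = int(na[best]) + (totA - int(nA[best]))
    in_A = np.zeros(2**k, dtype=bool)
    if correct_to_A > correct_to_a:
        in_A[best] = True
    else:
        in_A[:] = True
        in_A[best] = False
    gm = _grouping_from_masks(nA, na, in_A, k)
    return R2Result(r2, gm)


def model_r2(
    panel: HaplotypePanel, S: list[int] | tuple[int, ...], x: int, model: str
) -> R2Result:
    if model == COOCCURRENCE:
        return cooccurrence_r2(panel, S, x)
    if model == ONE_VS_REST:
        return one_vs_rest_r2(panel, S, x)
    raise ValueError(f"unknown model {model!r}")
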