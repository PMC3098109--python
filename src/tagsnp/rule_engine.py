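"""Tagging-rule generation.

Pipeline: merge SNPs in perfect LD (pairwise r² = 1) into equivalence
groups, enumerate candidate SNP sets over the group representatives under
the distance and size constraints, and emit non-redundant tagging rules
S → SNP_x (a rule is redundant when a proper subset of its left-hand side
already tags the same target).  Enumeration is size-layered so every
subset of a candidate set has been processed before the set itself, which
lets the redundancy check run *before* the r² computation via a per-target
hash of emitted left-hand sides.

Because positions are one-dimensional, "every pair within max_dist" is
simply "span <= max_dist".  A representative rule is emitted when some
choice of one member per group satisfies the span constraint; expansion to
member-level rules re-checks the constraint per instantiation.  Selection
(see greedy_selector) only uses rules whose representative positions
themselves satisfy the constraint, since tags are actual SNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .haplotype_io import HaplotypePanel, RunConfig
from .ld_models import (
    COOCCURRENCE,
    R2Result,
    cooccurrence_r2_many,
    model_r2,
    one_vs_rest_r2_many,
)


class RuleBudgetExceeded(RuntimeError):
    """Raised when the in-memory rule store outgrows config.rule_budget."""


@dataclass(frozen=True)
class EquivalenceGroup:
    """SNPs in mutual perfect LD, represented by their leftmost member."""

    representative: int
    members: tuple[int, ...]
    span: tuple[int, int]  # min/max member positions


@dataclass(eq=True)
class TaggingRule:
    """A rule lhs → rhs: the haplotypes over ``lhs`` predict ``rhs``.

    ``mapping`` sends each observed LHS haplotype, written as a tuple of
    allele symbols in lhs order, to the predicted RHS allele symbol.  It is
    frozen at training time and reused verbatim for prediction on other
    panels.
    """

    lhs: tuple[str, ...]
    rhs: str
    model: str
    r2: float
    mapping: dict[tuple[str, ...], str]

    def __len__(self) -> int:
        return len(self.lhs)


class RuleIndex:
    """Rules bucketed by target SNP, hashed on the left-hand side."""

    def __init__(self) -> None:
        self.buckets: dict[str, dict[frozenset, TaggingRule]] = {}
        self.n_rules = 0

    def add(self, rule: TaggingRule) -> None:
        self.buckets.setdefault(rule.rhs, {})[frozenset(rule.lhs)] = rule
        self.n_rules += 1

    def has_subset_rule(self, rhs: str, lhs: tuple[str, ...]) -> bool:
        """True if an emitted rule S' → rhs with S' a proper subset of lhs
        exists (at most 2^|lhs| − 2 lookups)."""
        bucket = self.buckets.get(rhs)
        if not bucket:
            return False
        for size in range(1, len(lhs)):
            for sub in itertools.combinations(lhs, size):
                if frozenset(sub) in bucket:
                    return True
        return False

    def rules(self):
        for bucket in self.buckets.values():
            yield from bucket.values()

    def rules_for(self, rhs: str) -> list[TaggingRule]:
        return list(self.buckets.get(rhs, {}).values())

    def __len__(self) -> int:
        return self.n_rules

    def per_length(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.rules():
            out[len(r)] = out.get(len(r), 0) + 1
        return out


@dataclass
class RuleStats:
    n_groups: int = 0
    n_rules: int = 0
    per_length: dict[int, int] = field(default_factory=dict)
    n_redundant_pruned: int = 0
    n_r2_evaluations: int = 0
    n_skipped_rhs: int = 0


def _perfect_ld(panel: HaplotypePanel, i: int, j: int) -> bool:
    """Exact r² = 1 test: columns identical or complementary (integer
    comparison, no floating point)."""
    ci, cj = panel.matrix[:, i], panel.matrix[:, j]
    return bool(np.array_equal(ci, cj) or np.array_equal(ci, 1 - cj))


def merge_equivalent_snps(panel: HaplotypePanel, max_dist: int) -> list[EquivalenceGroup]:
    """Left-to-right sweep merging SNPs in perfect LD.

    A SNP joins the leftmost existing group whose representative lies
    within max_dist and is in perfect LD with it; otherwise it founds a new
    group.  Anchoring on the representative bounds group spans and avoids
    unbounded chained groups.  Groups partition all SNPs.
    """
    pos = panel.positions
    groups: list[list[int]] = []
    reps: list[int] = []
    for j in range(panel.n_snps):
        placed = False
        for gi, rep in enumerate(reps):
            if pos[j] - pos[rep] > max_dist:
                continue
            if _perfect_ld(panel, rep, j):
                groups[gi].append(j)
                placed = True
                break
        if not placed:
            groups.append([j])
            reps.append(j)
    out = []
    for members in groups:
        ps = [int(pos[m]) for m in members]
        out.append(EquivalenceGroup(members[0], tuple(members), (min(ps), max(ps))))
    return out


def _feasible(position_lists: list[list[int]], max_dist: int) -> bool:
    """True if one position can be chosen from each list so that the overall
    span is <= max_dist (1-D: all-pairwise distance == span)."""
    # fast path: the representative/member-0 choice already fits
    firsts = [pl[0] for pl in position_lists]
    if max(firsts) - min(firsts) <= max_dist:
        return True
    for anchor in itertools.chain.from_iterable(position_lists):
        lo, hi = anchor, anchor + max_dist
        if all(any(lo <= p <= hi for p in pl) for pl in position_lists):
            return True
    return False


def _build_mapping(
    panel: HaplotypePanel, S: tuple[int, ...], x: int, res: R2Result
) -> dict[tuple[str, ...], str]:
    """Translate a grouping into an allele-symbol prediction mapping."""
    mapping: dict[tuple[str, ...], str] = {}
    gm = res.grouping
    if gm is None:
        return mapping
    for key in gm.group_A:
        mapping[tuple(panel.symbol(s, c) for s, c in zip(S, key))] = panel.symbol(x, 0)
    for key in gm.group_a:
        mapping[tuple(panel.symbol(s, c) for s, c in zip(S, key))] = panel.symbol(x, 1)
    return mapping


def enumerate_rules(
    panel: HaplotypePanel,
    groups: list[EquivalenceGroup],
    config: RunConfig,
    group_subset: list[int] | None = None,
    count_only: bool = False,
) -> tuple[RuleIndex, RuleStats]:
    """Enumerate non-redundant tagging rules over group representatives.

    Candidate sets are visited in deterministic order: by size (1, 2, ...,
    max_size), then lexicographically by representative index; target
    candidates in ascending index.  The redundancy check precedes the r²
    computation.  With config.skip_threshold set, a representative that has
    appeared as the target of that many emitted rules is excluded as a
    target for all subsequently visited candidate sets.

    ``group_subset`` restricts enumeration to the given group indices
    (used by chunked selection).  ``count_only`` disables the rule-budget
    signal (the index is still built; a production run would stream it to
    disk).
    """
    if group_subset is None:
        group_subset = list(range(len(groups)))
    sel = [groups[g] for g in group_subset]
    k = len(sel)
    member_pos = [[int(panel.positions[m]) for m in g.members] for g in sel]
    rep_ids = [panel.snps[g.representative].id for g in sel]

    index = RuleIndex()
    stats = RuleStats(n_groups=k)
    skipped: set[int] = set()
    rhs_counts: dict[int, int] = {}
    budget = None if count_only else config.rule_budget

    cooc = config.model == COOCCURRENCE
    rep_pos = np.asarray([member_pos[i][0] for i in range(k)], dtype=np.int64)
    multi = [len(member_pos[i]) > 1 for i in range(k)]

    def emit_for_set(idxs: tuple[int, ...], codes: np.ndarray) -> None:
        S_pos_lists = [member_pos[i] for i in idxs]
        S_snp = tuple(sel[i].representative for i in idxs)
        lhs_ids = tuple(rep_ids[i] for i in idxs)
        sz = len(idxs)
        lo = min(pl[0] for pl in S_pos_lists)
        hi = max(pl[0] for pl in S_pos_lists)
        S_multi = any(multi[i] for i in idxs)

        # filter target candidates first, then score them in one batch
        cands: list[int] = []
        for xi in range(k):
            if xi in idxs or xi in skipped:
                continue
            p = rep_pos[xi]
            if hi - p <= config.max_dist and p - lo <= config.max_dist:
                pass  # representative instantiation fits
            elif (S_multi or multi[xi]) and _feasible(
                S_pos_lists + [member_pos[xi]], config.max_dist
            ):
                pass  # some member instantiation fits
            else:
                continue
            if sz > 1 and index.has_subset_rule(rep_ids[xi], lhs_ids):
                stats.n_redundant_pruned += 1
                continue
            cands.append(xi)
        if not cands:
            return

        X = [sel[xi].representative for xi in cands]
        m = len(cands)
        width = 2 ** (sz + 1)
        joint = codes[:, None] * 2 + panel.matrix[:, X]
        joint += np.arange(m, dtype=np.int64) * width
        counts = np.bincount(joint.ravel(order="F"), minlength=m * width)
        counts = counts.reshape(m, width // 2, 2)
        r2s = cooccurrence_r2_many(counts) if cooc else one_vs_rest_r2_many(counts)
        stats.n_r2_evaluations += m

        for xi, x_snp, r2 in zip(cands, X, r2s):
            if r2 < config.min_r2:
                continue
            # full result only for emitted rules (same value, adds grouping)
            res = model_r2(panel, S_snp, x_snp, config.model)
            rule = TaggingRule(
                lhs_ids,
                rep_ids[xi],
                config.model,
                res.r2,
                _build_mapping(panel, S_snp, x_snp, res),
            )
            index.add(rule)
            if budget is not None and index.n_rules > budget:
                raise RuleBudgetExceeded(
                    f"rule budget {budget} exceeded during enumeration"
                )
            rhs_counts[xi] = rhs_counts.get(xi, 0) + 1
            if (
                config.skip_threshold is not None
                and rhs_counts[xi] >= config.skip_threshold
            ):
                skipped.add(xi)

    def extend(
        prefix: tuple[int, ...], codes: np.ndarray | None, start: int, size: int
    ) -> None:
        if len(prefix) == size:
            emit_for_set(prefix, codes)
            return
        for nxt in range(start, k):
            pls = [member_pos[i] for i in prefix] + [member_pos[nxt]]
            if not _feasible(pls, config.max_dist):
                continue
            col = panel.matrix[:, sel[nxt].representative].astype(np.int64)
            nxt_codes = col if codes is None else codes * 2 + col
            extend(prefix + (nxt,), nxt_codes, nxt + 1, size)

    for size in range(1, config.max_size + 1):
        extend((), None, 0, size)

    stats.n_rules = index.n_rules
    stats.per_length = index.per_length()
    stats.n_skipped_rhs = len(skipped)
    return index, stats


def _column_orientation(panel: HaplotypePanel, a: int, b: int) -> bool:
    """True if columns a and b are identical (major↔major), False if
    complementary.  Only meaningful for members of one equivalence group."""
    return bool(np.array_equal(panel.matrix[:, a], panel.matrix[:, b]))


def _relabel_rhs(
    rule: TaggingRule, panel: HaplotypePanel, member: int, same: bool
) -> dict[tuple[str, ...], str]:
    """Rewrite the mapping's predicted symbols for an equivalent RHS member."""
    rep_idx = panel.index_of(rule.rhs)
    rep = panel.snps[rep_idx]
    mem = panel.snps[member]
    if same:
        trans = {rep.major_allele: mem.major_allele, rep.minor_allele: mem.minor_allele}
    else:
        trans = {rep.major_allele: mem.minor_allele, rep.minor_allele: mem.major_allele}
    return {k: trans[v] for k, v in rule.mapping.items()}


def expand_rule_for_member(
    rule: TaggingRule,
    member: int,
    groups: list[EquivalenceGroup],
    panel: HaplotypePanel,
    max_dist: int,
) -> TaggingRule | None:
    """Instantiate a representative rule for one member of its RHS group.

    Returns the member-level rule iff every pair among lhs ∪ {member}
    satisfies the distance constraint; otherwise None.  The r² is unchanged
    (equivalent SNPs have identical statistics); the mapping's predicted
    symbols are relabelled through the member's alleles.
    """
    rhs_idx = panel.index_of(rule.rhs)
    group = next((g for g in groups if rhs_idx in g.members), None)
    if group is None or member not in group.members:
        raise ValueError(f"SNP index {member} is not in the group of {rule.rhs}")
    pos = panel.positions
    pts = [int(pos[panel.index_of(i)]) for i in rule.lhs] + [int(pos[member])]
    if max(pts) - min(pts) > max_dist:
        return None
    if member == rhs_idx:
        return rule
    same = _column_orientation(panel, rhs_idx, member)
    return TaggingRule(
        rule.lhs,
        panel.snps[member].id,
        rule.model,
        rule.r2,
        _relabel_rhs(rule, panel, member, same),
    )


def _relabel_lhs_key(
    panel: HaplotypePanel, rep_idx: int, mem_idx: int, symbol: str
) -> str:
    rep, mem = panel.snps[rep_idx], panel.snps[mem_idx]
    same = _column_orientation(panel, rep_idx, mem_idx)
    if symbol == rep.major_allele:
        return mem.major_allele if same else mem.minor_allele
    return mem.minor_allele if same else mem.major_allele


def expand_all_rules(
    index: RuleIndex,
    groups: list[EquivalenceGroup],
    panel: HaplotypePanel,
    max_dist: int,
) -> list[TaggingRule]:
    """Full member-level rule set represented by the representative rules.

    Substitutes every member combination on both sides of every rule,
    keeps distance-valid instantiations, and adds the within-group perfect
    rules (r² = 1 between distance-valid members of one group) that have
    no representative-level counterpart.  Together with non-redundant
    enumeration this reproduces exactly the non-redundant rule set of an
    unmerged run.
    """
    pos = panel.positions
    out: dict[tuple[frozenset, str], TaggingRule] = {}

    # within-group perfect pairwise rules
    for g in groups:
        for m1, m2 in itertools.permutations(g.members, 2):
            if abs(int(pos[m1]) - int(pos[m2])) > max_dist:
                continue
            s1, s2 = panel.snps[m1], panel.snps[m2]
            same = _column_orientation(panel, m1, m2)
            mapping = {
                (s1.major_allele,): s2.major_allele if same else s2.minor_allele,
                (s1.minor_allele,): s2.minor_allele if same else s2.major_allele,
            }
            rule = TaggingRule((s1.id,), s2.id, "equivalence", 1.0, mapping)
            out[(frozenset(rule.lhs), rule.rhs)] = rule

    group_of: dict[int, EquivalenceGroup] = {}
    for g in groups:
        for m in g.members:
            group_of[m] = g

    for rule in index.rules():
        lhs_idx = [panel.index_of(i) for i in rule.lhs]
        rhs_idx = panel.index_of(rule.rhs)
        lhs_groups = [group_of[i] for i in lhs_idx]
        rhs_group = group_of[rhs_idx]
        for combo in itertools.product(*(g.members for g in lhs_groups)):
            for rhs_m in rhs_group.members:
                pts = [int(pos[m]) for m in combo] + [int(pos[rhs_m])]
                if max(pts) - min(pts) > max_dist:
                    continue
                rep = panel.snps[rhs_idx]
                mem = panel.snps[rhs_m]
                if _column_orientation(panel, rhs_idx, rhs_m):
                    trans = {rep.major_allele: mem.major_allele,
                             rep.minor_allele: mem.minor_allele}
                else:
                    trans = {rep.major_allele: mem.minor_allele,
                             rep.minor_allele: mem.major_allele}
                mapping = {
                    tuple(
                        _relabel_lhs_key(panel, ri, mi, sym)
                        for ri, mi, sym in zip(lhs_idx, combo, key)
                    ): trans[val]
                    for key, val in rule.mapping.items()
                }
                new_rule = TaggingRule(
                    tuple(panel.snps[m].id for m in combo),
                    panel.snps[rhs_m].id,
                    rule.model,
                    rule.r2,
                    mapping,
                )
                out[(frozenset(new_rule.lhs), new_rule.rhs)] = new_rule
    return list(out.values())
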