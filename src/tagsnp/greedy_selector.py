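"""Greedy tag-SNP selection over tagging rules.

A SNP is *covered* when it is itself a tag or when some rule S → SNP with
S a subset of the selected tag set T exists.  Selection starts from the
mandatory tags (SNPs that are the target of no rule), then repeatedly
picks the candidate covering the most uncovered SNPs (ties broken toward
the smaller genomic position) until everything is covered.

Memory-bounded runs split the chromosome into chunks: forced breakpoints
at adjacent-SNP gaps larger than max_dist (such SNPs cannot interact), and
further cuts wherever the accumulated rule count would exceed the rule
budget.  Adjacent chunks overlap by the SNPs within max_dist of the next
chunk's first new SNP, and tags selected in the overlap carry over.

Selection operates on equivalence-group representatives; afterwards each
non-representative member is checked for a distance-valid member-level
rule and promoted to a tag when none exists, which makes the full-coverage
invariant exact at the individual-SNP level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_io import HaplotypePanel, RunConfig
from .ld_models import model_r2
from .rule_engine import (
    EquivalenceGroup,
    RuleIndex,
    TaggingRule,
    enumerate_rules,
    expand_rule_for_member,
)


@dataclass
class CoverageState:
    """Outcome of a selection run: the C/T/V bookkeeping, final form."""

    tags: list[str] = field(default_factory=list)
    mandatory: set[str] = field(default_factory=set)
    uncovered: set[str] = field(default_factory=set)
    covered_via: dict[str, TaggingRule | None] = field(default_factory=dict)
    chunk_of: dict[str, int] = field(default_factory=dict)
    n_chunks: int = 1
    n_rules_used: int = 0


@dataclass(frozen=True)
class Chunk:
    """Contiguous representative index range [start, end]; indices below
    ``new_start`` form the overlap inherited from the previous chunk."""

    start: int
    end: int
    new_start: int


def rule_span_ok(rule: TaggingRule, panel: HaplotypePanel, max_dist: int) -> bool:
    """Distance validity of a rule at the positions of its named SNPs."""
    pos = panel.positions
    pts = [int(pos[panel.index_of(i)]) for i in (*rule.lhs, rule.rhs)]
    return max(pts) - min(pts) <= max_dist


def mandatory_tags(rules, all_snps) -> set[str]:
    """SNP ids never appearing as the target of any rule: forced tags."""
    targets = {r.rhs for r in rules}
    return {s for s in all_snps if s not in targets}


def covered_by_candidate(
    snp_j: str, snp_i: str, tags: set[str], rules_for_j: list[TaggingRule]
) -> bool:
    """Reference predicate: does picking snp_i (given tags T) cover snp_j?

    True iff snp_j == snp_i (self-coverage) or some rule lhs → snp_j has
    snp_i ∈ lhs and lhs ⊆ T ∪ {snp_i}.
    """
    if snp_j == snp_i:
        return True
    aug = tags | {snp_i}
    return any(snp_i in r.lhs and set(r.lhs) <= aug for r in rules_for_j)


def _greedy_core(
    rep_ids: list[str],
    rules: list[TaggingRule],
    panel: HaplotypePanel,
    carried: list[str] | None = None,
    already_covered: set[str] | None = None,
) -> tuple[list[str], set[str], dict[str, TaggingRule | None]]:
    """Greedy covering over representatives.

    Returns (tags in pick order, mandatory set, covered_via).  ``carried``
    seeds T (tags inherited from a previous chunk); ``already_covered``
    SNPs are exempt from coverage (covered in a previous chunk).
    """
    pos = {s: int(panel.positions[panel.index_of(s)]) for s in rep_ids}
    carried = sorted(carried or [], key=lambda s: pos.get(s, 0))
    tags = list(carried)
    tag_set = set(tags)
    covered_via: dict[str, TaggingRule | None] = {}

    rules_by_rhs: dict[str, list[TaggingRule]] = {}
    for r in rules:
        rules_by_rhs.setdefault(r.rhs, []).append(r)

    V = {s for s in rep_ids if s not in tag_set}
    if already_covered:
        V -= already_covered

    mand = {j for j in V if not rules_by_rhs.get(j)}
    for j in sorted(mand, key=pos.get):
        tags.append(j)
        tag_set.add(j)
        covered_via[j] = None
    V -= mand

    # initial sweep: SNPs already tagged by subsets of T (carried + mandatory)
    for j in sorted(V, key=pos.get):
        for r in rules_by_rhs.get(j, ()):
            if set(r.lhs) <= tag_set:
                V.discard(j)
                covered_via[j] = r
                break

    while V:
        gains: dict[str, set[str]] = {}
        gain_rule: dict[str, dict[str, TaggingRule]] = {}
        for j in V:
            gains.setdefault(j, set()).add(j)  # self-coverage
            for r in rules_by_rhs.get(j, ()):
                missing = [s for s in r.lhs if s not in tag_set]
                if len(missing) == 1:
                    i = missing[0]
                    gains.setdefault(i, set()).add(j)
                    gain_rule.setdefault(i, {}).setdefault(j, r)
        best = max(gains, key=lambda i: (len(gains[i]), -pos[i]))
        tags.append(best)
        tag_set.add(best)
        for j in gains[best]:
            V.discard(j)
            if j == best:
                covered_via[j] = None
            else:
                covered_via[j] = gain_rule[best][j]
    return tags, mand, covered_via


def _expand_member_coverage(
    panel: HaplotypePanel,
    groups: list[EquivalenceGroup],
    rules: list[TaggingRule],
    state: CoverageState,
    config: RunConfig,
) -> None:
    """Extend representative-level coverage to every group member.

    A member is covered when its representative is a tag (perfect pairwise
    rule, distance-valid by group construction) or when a covering rule of
    the representative expands to a distance-valid member-level rule;
    failing members are promoted to tags.
    """
    tag_set = set(state.tags)
    rules_by_rhs: dict[str, list[TaggingRule]] = {}
    for r in rules:
        rules_by_rhs.setdefault(r.rhs, []).append(r)
    promoted: list[tuple[int, str, str]] = []
    for g in groups:
        rep_id = panel.snps[g.representative].id
        for m in g.members:
            if m == g.representative:
                continue
            m_id = panel.snps[m].id
            if rep_id in tag_set:
                continue  # {rep} -> member, r2 = 1, within max_dist of rep
            ok = False
            for r in rules_by_rhs.get(rep_id, ()):
                if set(r.lhs) <= tag_set:
                    expanded = expand_rule_for_member(
                        r, m, groups, panel, config.max_dist
                    )
                    if expanded is not None:
                        state.covered_via[m_id] = expanded
                        ok = True
                        break
            if not ok:
                promoted.append((int(panel.positions[m]), m_id, rep_id))
    for _, m_id, rep_id in sorted(promoted):
        state.tags.append(m_id)
        state.covered_via[m_id] = None
        state.chunk_of[m_id] = state.chunk_of.get(rep_id, 0)


def select_tags_greedy(
    index: RuleIndex,
    panel: HaplotypePanel,
    groups: list[EquivalenceGroup],
    config: RunConfig,
) -> CoverageState:
    """Single-chunk greedy selection (see module docstring)."""
    rep_ids = [panel.snps[g.representative].id for g in groups]
    valid = [r for r in index.rules() if rule_span_ok(r, panel, config.max_dist)]
    tags, mand, covered_via = _greedy_core(rep_ids, valid, panel)
    state = CoverageState(
        tags=tags,
        mandatory=mand | set(),
        covered_via=covered_via,
        n_rules_used=len(valid),
    )
    state.chunk_of = {t: 0 for t in tags}
    _expand_member_coverage(panel, groups, valid, state, config)
    return state


def partition_chunks(
    positions: np.ndarray,
    rule_budget: int | None,
    max_dist: int,
    rule_counts: list[int] | None = None,
) -> list[Chunk]:
    """Split an ordered SNP track into chunks.

    Forced breakpoints at adjacent gaps > max_dist; with a finite budget,
    further cuts when the accumulated rule count (``rule_counts[i]`` =
    rules attributed to SNP i, by rightmost involved SNP) would exceed it.
    Each chunk starts with the overlap: the SNPs of the previous chunk
    within max_dist of its first new SNP.
    """
    n = len(positions)
    if rule_counts is None:
        rule_counts = [0] * n
    chunks: list[Chunk] = []
    start = new_start = 0
    acc = 0
    for i in range(n):
        if i > 0 and positions[i] - positions[i - 1] > max_dist:
            chunks.append(Chunk(start, i - 1, new_start))
            start = new_start = i
            acc = rule_counts[i]
            continue
        if rule_budget is not None:
            if acc + rule_counts[i] > rule_budget:
                if i == new_start:
                    raise ValueError(
                        f"rule budget {rule_budget} too small: SNP index {i} alone "
                        f"accounts for {rule_counts[i]} rules"
                    )
                chunks.append(Chunk(start, i - 1, new_start))
                new_start = i
                start = int(np.searchsorted(positions, positions[i] - max_dist))
                acc = sum(rule_counts[start : i + 1])
                continue
        acc += rule_counts[i]
    chunks.append(Chunk(start, n - 1, new_start))
    return chunks


def select_tags_chunked(
    panel: HaplotypePanel,
    groups: list[EquivalenceGroup],
    config: RunConfig,
) -> CoverageState:
    """Memory-bounded selection: enumerate and cover chunk by chunk.

    A counting enumeration per gap-delimited segment (rules attributed to
    their rightmost SNP, as known after the rule-generation step) drives
    the budget cuts; each chunk then re-enumerates only its own rules.
    Tags selected in a chunk's overlap carry into the next chunk, and SNPs
    covered by an earlier chunk are not re-covered.  With an unlimited
    budget and no gaps this reduces to a single chunk and is identical to
    :func:`select_tags_greedy`.
    """
    rep_pos = np.asarray([int(panel.positions[g.representative]) for g in groups])
    rep_ids = [panel.snps[g.representative].id for g in groups]
    n = len(groups)

    # counting pass per gap-delimited segment
    counts = [0] * n
    seg_start = 0
    segments = []
    for i in range(1, n + 1):
        if i == n or rep_pos[i] - rep_pos[i - 1] > config.max_dist:
            segments.append((seg_start, i - 1))
            seg_start = i
    pos_to_idx = {int(p): i for i, p in enumerate(rep_pos)}
    for s, e in segments:
        idx, _ = enumerate_rules(
            panel, groups, config, group_subset=list(range(s, e + 1)), count_only=True
        )
        for r in idx.rules():
            rightmost = max(
                int(panel.positions[panel.index_of(i)]) for i in (*r.lhs, r.rhs)
            )
            counts[pos_to_idx[rightmost]] += 1

    chunks = partition_chunks(rep_pos, config.rule_budget, config.max_dist, counts)

    state = CoverageState(n_chunks=len(chunks))
    tag_set: set[str] = set()
    covered: set[str] = set()
    all_valid: list[TaggingRule] = []
    seen_rule_keys: set[tuple[frozenset, str]] = set()
    for ci, chunk in enumerate(chunks):
        sub = list(range(chunk.start, chunk.end + 1))
        idx, _ = enumerate_rules(panel, groups, config, group_subset=sub, count_only=True)
        chunk_ids = [rep_ids[i] for i in sub]
        valid = [r for r in idx.rules() if rule_span_ok(r, panel, config.max_dist)]
        for r in valid:
            key = (frozenset(r.lhs), r.rhs)
            if key not in seen_rule_keys:
                seen_rule_keys.add(key)
                all_valid.append(r)
        carried = [t for t in tag_set if t in set(chunk_ids)]
        tags, mand, covered_via = _greedy_core(
            chunk_ids, valid, panel, carried=carried, already_covered=covered
        )
        for t in tags:
            if t not in tag_set:
                tag_set.add(t)
                state.tags.append(t)
                state.chunk_of[t] = ci
        state.mandatory |= mand
        for j, r in covered_via.items():
            if j not in state.covered_via:
                state.covered_via[j] = r
        covered |= set(covered_via) | set(tags)
    state.n_rules_used = len(all_valid)
    _expand_member_coverage(panel, groups, all_valid, state, config)
    return state


def verify_full_coverage(
    panel: HaplotypePanel,
    state: CoverageState,
    config: RunConfig,
) -> list[str]:
    """Independent coverage audit at the individual-SNP level.

    For every SNP of the (MAF-filtered) panel not in the tag set, search
    exhaustively for a subset S of the tags with |S| <= max_size, span of
    S ∪ {SNP} <= max_dist and model r² >= min_r2, recomputing r² from the
    matrix.  Returns the ids left uncovered (empty on success).  This
    deliberately ignores the selector's bookkeeping.
    """
    import itertools as it

    tag_idx = sorted(panel.index_of(t) for t in set(state.tags))
    tag_pos = [int(panel.positions[i]) for i in tag_idx]
    uncovered = []
    for j in range(panel.n_snps):
        sid = panel.snps[j].id
        if sid in set(state.tags):
            continue
        pj = int(panel.positions[j])
        near = [
            t
            for t, p in zip(tag_idx, tag_pos)
            if abs(p - pj) <= config.max_dist and t != j
        ]
        found = False
        for size in range(1, config.max_size + 1):
            for S in it.combinations(near, size):
                pts = [int(panel.positions[s]) for s in S] + [pj]
                if max(pts) - min(pts) > config.max_dist:
                    continue
                res = model_r2(panel, S, j, config.model)
                if res.defined and res.r2 >= config.min_r2:
                    found = True
                    break
            if found:
                break
        if not found:
            uncovered.append(sid)
    return uncovered
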