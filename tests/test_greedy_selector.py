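"""Greedy covering, mandatory tags, chunking, full-coverage audits."""

import itertools

import numpy as np
import pytest

from tagsnp import (
    RuleIndex,
    RunConfig,
    TaggingRule,
    covered_by_candidate,
    enumerate_rules,
    filter_by_maf,
    mandatory_tags,
    merge_equivalent_snps,
    partition_chunks,
    select_tags_chunked,
    select_tags_greedy,
    simulate_panel,
    verify_full_coverage,
)
from tagsnp.synthetic_data import SimSpec

from conftest import make_panel


def simple_rule(lhs, rhs):
    return TaggingRule(tuple(lhs), rhs, "cooccurrence", 1.0, {})


def index_of(rules):
    idx = RuleIndex()
    for r in rules:
        idx.add(r)
    return idx


def prepared(
    seed,
    n_snps=30,
    min_r2=0.9,
    max_size=3,
    max_dist=100_000,
    skip=None,
    budget=None,
    **sim,
):
    panel = filter_by_maf(simulate_panel(SimSpec(seed=seed, n_snps=n_snps, **sim)), 0.05)
    cfg = RunConfig(
        min_r2=min_r2,
        max_size=max_size,
        max_dist=max_dist,
        skip_threshold=skip,
        rule_budget=budget,
    )
    groups = merge_equivalent_snps(panel, cfg.max_dist)
    return panel, groups, cfg


class TestMandatoryTags:
    def test_empty_rule_set_makes_everything_mandatory(self):
        assert mandatory_tags([], ["s1", "s2"]) == {"s1", "s2"}

    def test_non_targets_are_mandatory(self):
        rules = [simple_rule(["s1"], "s2"), simple_rule(["s3"], "s4")]
        assert mandatory_tags(rules, ["s1", "s2", "s3", "s4"]) == {"s1", "s3"}

    def test_all_targets_means_none_mandatory(self):
        rules = [simple_rule(["s2"], "s1"), simple_rule(["s1"], "s2")]
        assert mandatory_tags(rules, ["s1", "s2"]) == set()


class TestCoveredByCandidate:
    def test_candidate_completes_partial_tag_set(self):
        rule = simple_rule(["s1", "s2"], "s3")
        assert covered_by_candidate("s3", "s2", {"s1"}, [rule])

    def test_candidate_alone_is_not_enough(self):
        rule = simple_rule(["s1", "s2"], "s3")
        assert not covered_by_candidate("s3", "s2", set(), [rule])

    def test_self_coverage(self):
        assert covered_by_candidate("s2", "s2", set(), [])


def distinct_panel(n_snps: int, seed: int = 0):
    """Random panel guaranteed to have only singleton equivalence groups."""
    rng = np.random.default_rng(seed)
    while True:
        codes = rng.integers(0, 2, size=(10, n_snps)).astype(np.uint8)
        if any(len(set(codes[:, j])) < 2 for j in range(n_snps)):
            continue
        panel = make_panel(codes)
        if len(merge_equivalent_snps(panel, 10**9)) == n_snps:
            return panel


class TestGreedySelection:
    def test_mandatory_seeds_and_rules_cover_the_rest(self):
        panel = distinct_panel(4)
        idx = index_of([simple_rule(["s1"], "s2"), simple_rule(["s3"], "s4")])
        groups = merge_equivalent_snps(panel, 100_000)
        state = select_tags_greedy(idx, panel, groups, RunConfig(max_dist=100_000))
        assert state.tags == ["s1", "s3"]
        assert state.mandatory == {"s1", "s3"}
        assert not state.uncovered

    def test_no_rules_selects_every_snp(self):
        panel = distinct_panel(3)
        groups = merge_equivalent_snps(panel, 100_000)
        state = select_tags_greedy(index_of([]), panel, groups, RunConfig())
        assert state.tags == ["s1", "s2", "s3"]

    def test_picks_highest_coverage_candidate_first(self):
        # s2 covers three targets plus s1; s1 only covers s6 and s2
        rules = [
            simple_rule(["s2"], "s3"),
            simple_rule(["s2"], "s4"),
            simple_rule(["s2"], "s5"),
            simple_rule(["s1"], "s6"),
            simple_rule(["s2"], "s1"),
            simple_rule(["s1"], "s2"),
        ]
        panel = distinct_panel(6)
        groups = merge_equivalent_snps(panel, 100_000)
        state = select_tags_greedy(index_of(rules), panel, groups, RunConfig())
        assert state.tags == ["s2", "s1"]
        assert not state.uncovered

    def test_tie_breaks_toward_smaller_position(self):
        # after mandatory s3 covers s4, candidates s1 and s2 both cover two
        # SNPs (self + the other); the leftmost wins
        rules = [
            simple_rule(["s1"], "s2"),
            simple_rule(["s2"], "s1"),
            simple_rule(["s3"], "s4"),
        ]
        panel = distinct_panel(4)
        groups = merge_equivalent_snps(panel, 100_000)
        state = select_tags_greedy(index_of(rules), panel, groups, RunConfig())
        assert state.tags == ["s3", "s1"]

    @pytest.mark.parametrize("seed", range(8))
    def test_full_coverage_verified_independently(self, seed):
        panel, groups, cfg = prepared(seed, n_equivalent_pairs=2)
        index, _ = enumerate_rules(panel, groups, cfg)
        state = select_tags_greedy(index, panel, groups, cfg)
        assert verify_full_coverage(panel, state, cfg) == []

    def test_greedy_within_envelope_of_exhaustive_optimum(self):
        for seed in range(10):
            panel, groups, cfg = prepared(
                seed, n_snps=12, n_haplotypes=40, min_r2=0.8, mean_block_length=4
            )
            index, _ = enumerate_rules(panel, groups, cfg)
            state = select_tags_greedy(index, panel, groups, cfg)
            opt = exhaustive_min_tags(panel, groups, index, cfg)
            assert opt <= len(state.tags) <= opt + 2

    def test_deterministic(self):
        states = []
        for _ in range(2):
            panel, groups, cfg = prepared(13)
            index, _ = enumerate_rules(panel, groups, cfg)
            states.append(select_tags_greedy(index, panel, groups, cfg).tags)
        assert states[0] == states[1]


def exhaustive_min_tags(panel, groups, index, cfg) -> int:
    """Smallest tag set achieving full coverage, by brute-force search over
    representative subsets (bitmask set cover; member expansion follows the
    same promote-on-failure policy as the selector)."""
    from tagsnp.greedy_selector import rule_span_ok
    from tagsnp.rule_engine import expand_rule_for_member

    rep_ids = [panel.snps[g.representative].id for g in groups]
    valid = [r for r in index.rules() if rule_span_ok(r, panel, cfg.max_dist)]
    by_rhs = {}
    for r in valid:
        by_rhs.setdefault(r.rhs, []).append(r)

    def n_tags_with(chosen: set) -> int | None:
        for j in rep_ids:
            if j in chosen:
                continue
            if not any(set(r.lhs) <= chosen for r in by_rhs.get(j, ())):
                return None
        extra = 0
        for g in groups:
            rep_id = panel.snps[g.representative].id
            for m in g.members:
                if m == g.representative or rep_id in chosen:
                    continue
                ok = any(
                    set(r.lhs) <= chosen
                    and expand_rule_for_member(r, m, groups, panel, cfg.max_dist)
                    is not None
                    for r in by_rhs.get(rep_id, ())
                )
                if not ok:
                    extra += 1
        return len(chosen) + extra

    best = None
    for size in range(0, len(rep_ids) + 1):
        for combo in itertools.combinations(rep_ids, size):
            total = n_tags_with(set(combo))
            if total is not None:
                best = total if best is None else min(best, total)
        if best is not None and best <= size:
            return best
    return best


class TestPartitionChunks:
    def test_gap_forces_breakpoint_without_overlap(self):
        pos = np.array([1000, 25_000, 50_000, 200_000, 225_000, 250_000])
        chunks = partition_chunks(pos, None, 100_000)
        assert len(chunks) == 2
        assert (chunks[0].start, chunks[0].end) == (0, 2)
        assert (chunks[1].start, chunks[1].end, chunks[1].new_start) == (3, 5, 3)

    def test_unlimited_budget_no_gaps_single_chunk(self):
        pos = np.arange(10) * 1000 + 1
        chunks = partition_chunks(pos, None, 100_000)
        assert len(chunks) == 1

    def test_budget_cuts_cover_everything_with_overlap(self):
        pos = np.arange(30) * 2000 + 1
        counts = [4] * 30
        chunks = partition_chunks(pos, 40, 10_000, counts)
        assert len(chunks) >= 3
        covered = set()
        for c in chunks:
            covered |= set(range(c.start, c.end + 1))
        assert covered == set(range(30))
        for prev, nxt in zip(chunks, chunks[1:]):
            # overlap = SNPs within max_dist of the first new SNP
            expect_start = int(np.searchsorted(pos, pos[nxt.new_start] - 10_000))
            assert nxt.start == expect_start
            assert prev.end == nxt.new_start - 1

    def test_budget_too_small_raises(self):
        pos = np.array([1000, 2000])
        with pytest.raises(ValueError, match="budget"):
            partition_chunks(pos, 0, 100_000, [1, 1])


class TestChunkedSelection:
    def test_single_chunk_reduces_to_greedy(self):
        panel, groups, cfg = prepared(17)
        index, _ = enumerate_rules(panel, groups, cfg)
        greedy = select_tags_greedy(index, panel, groups, cfg)
        chunked = select_tags_chunked(panel, groups, cfg)
        assert chunked.n_chunks == 1
        assert chunked.tags == greedy.tags

    def test_budget_forces_chunks_and_coverage_holds(self):
        # max_dist well below the chromosome span: the regime chunking is for
        panel, groups, cfg = prepared(
            23, n_snps=60, budget=30, min_r2=0.85, max_dist=20_000
        )
        state = select_tags_chunked(panel, groups, cfg)
        assert state.n_chunks >= 3
        assert verify_full_coverage(panel, state, cfg) == []

    def test_overlap_tags_counted_once(self):
        panel, groups, cfg = prepared(29, n_snps=40, budget=30, max_dist=20_000)
        state = select_tags_chunked(panel, groups, cfg)
        assert len(state.tags) == len(set(state.tags))

    def test_chunked_tag_count_close_to_unchunked(self):
        # chunks must be large relative to the max_dist window for the
        # boundary overhead to stay small (the regime chunking targets)
        incs = []
        for seed in range(3):
            panel, groups, cfg = prepared(
                seed, n_snps=200, min_r2=0.9, max_size=2, max_dist=20_000
            )
            index, _ = enumerate_rules(panel, groups, cfg)
            base = len(select_tags_greedy(index, panel, groups, cfg).tags)
            cfg_b = RunConfig(
                min_r2=0.9, max_size=2, max_dist=20_000, rule_budget=60
            )
            state = select_tags_chunked(panel, groups, cfg_b)
            assert state.n_chunks >= 2
            assert verify_full_coverage(panel, state, cfg_b) == []
            incs.append((len(state.tags) - base) / base)
        assert np.mean(incs) <= 0.05
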