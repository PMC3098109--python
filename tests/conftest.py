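"""Shared fixtures and panel-building helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tagsnp.haplotype_io import HaplotypePanel, panel_from_alleles
from tagsnp.ld_models import model_r2


def make_panel(
    codes,
    positions=None,
    alleles=None,
    ids=None,
) -> HaplotypePanel:
    """Panel from a raw 0/1 matrix (rows = haplotypes).

    Default alleles are (A, a), (B, b), ... so columns read like the
    classic two-locus notation; code 0 is recoded to the major allele by
    the panel constructor.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    n_snps = codes.shape[1]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(n_snps)]
    if alleles is None:
        letters = "ABCDEFGHJKLMNPQRSTUVWXYZ"
        alleles = [(letters[j], letters[j].lower()) for j in range(n_snps)]
    if ids is None:
        ids = [f"s{j + 1}" for j in range(n_snps)]
    return panel_from_alleles(ids, positions, alleles, codes)


def two_locus_panel(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> HaplotypePanel:
    """Panel realizing given two-locus haplotype counts."""
    rows = (
        [[0, 0]] * n_AB + [[0, 1]] * n_Ab + [[1, 0]] * n_aB + [[1, 1]] * n_ab
    )
    return make_panel(rows)


def random_panel(seed: int, n_hap: int = 40, n_snps: int = 8) -> HaplotypePanel:
    """iid random bi-allelic panel (low LD; for algebraic property tests)."""
    rng = np.random.default_rng(seed)
    while True:
        codes = rng.integers(0, 2, size=(n_hap, n_snps)).astype(np.uint8)
        if all(0 < codes[:, j].sum() < n_hap for j in range(n_snps)):
            return make_panel(codes)


def brute_force_rules(panel, config) -> dict:
    """Member-level oracle for rule generation: test every subset without
    merging, then drop redundant rules.  Returns {(lhs ids, rhs id): r2}."""
    n = panel.n_snps
    pos = panel.positions
    kept = {}
    for size in range(1, config.max_size + 1):
        for S in itertools.combinations(range(n), size):
            for x in range(n):
                if x in S:
                    continue
                pts = [int(pos[s]) for s in S] + [int(pos[x])]
                if max(pts) - min(pts) > config.max_dist:
                    continue
                res = model_r2(panel, S, x, config.model)
                if res.defined and res.r2 >= config.min_r2:
                    key = (frozenset(panel.snps[s].id for s in S), panel.snps[x].id)
                    kept[key] = res.r2
    out = {}
    for (lhs, rhs), r2 in kept.items():
        redundant = any(
            (frozenset(sub), rhs) in kept
            for sz in range(1, len(lhs))
            for sub in itertools.combinations(sorted(lhs), sz)
        )
        if not redundant:
            out[(lhs, rhs)] = r2
    return out


@pytest.fixture
def tmp_panel_files(tmp_path):
    """Write-and-return paths helper for legend/haps pairs."""

    def _write(panel, stem="panel"):
        from tagsnp.haplotype_io import write_panel

        legend = tmp_path / f"{stem}.legend"
        haps = tmp_path / f"{stem}.haps"
        write_panel(panel, legend, haps)
        return legend, haps

    return _write
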