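"""Synthetic phased haplotype panels with block-wise LD.

The generator is a founder-template mosaic, not a coalescent model: each
LD block draws a small number of founder haplotypes, and every sample
haplotype copies one founder through the block, switching founders between
adjacent SNPs with a small probability.  This produces the features the
tagging method exploits — strong LD and perfect-LD equivalences inside
blocks, near-independence across blocks, and a controllable MAF spectrum —
without recombination maps or demography.  It is a test fixture with
realistic structure, not a population-genetics simulator.

Defaults describe a HapMap-like panel at desk scale: 120 haplotypes
(60 diploid individuals), blocks of ~8 SNPs with ~5 common founder
haplotypes each, a 3% mosaic (effective recombination/mutation) rate,
SNPs a few kb apart, and a 5% MAF floor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .haplotype_io import HaplotypePanel, panel_from_alleles

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated panel (all randomness from ``seed``)."""

    n_haplotypes: int = 120
    n_snps: int = 60
    mean_block_length: int = 8
    n_founders: int = 5
    mosaic_rate: float = 0.03
    maf_min: float = 0.05
    n_equivalent_pairs: int = 0
    spacing_mean: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mosaic_rate <= 1.0):
            raise ValueError("mosaic_rate must be in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.n_haplotypes < 2 or self.n_snps < 1:
            raise ValueError("need >= 2 haplotypes and >= 1 SNP")
        if self.maf_min > 0 and round(self.n_haplotypes * self.maf_min) < 1:
            raise ValueError("maf_min infeasible for this panel size")


def _draw_column(
    rng: np.random.Generator, founder_of: np.ndarray, n_founders: int, maf_min: float
) -> np.ndarray:
    """Draw founder alleles for one SNP so the resulting column passes the
    MAF floor given the haplotype→founder assignment."""
    n = len(founder_of)
    for _ in range(200):
        alleles = rng.integers(0, 2, size=n_founders)
        if alleles.min() == alleles.max():
            continue
        col = alleles[founder_of]
        maf = min(col.mean(), 1 - col.mean())
        if maf >= maf_min:
            return col.astype(np.uint8)
    raise ValueError(
        "cannot satisfy maf_min: founder usage too skewed (infeasible SimSpec)"
    )


def simulate_panel(spec: SimSpec) -> HaplotypePanel:
    """Generate a panel per the founder-mosaic model (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)

    # block lengths
    lengths: list[int] = []
    while sum(lengths) < spec.n_snps:
        lengths.append(1 + int(rng.poisson(max(spec.mean_block_length - 1, 0))))
    lengths[-1] -= sum(lengths) - spec.n_snps
    if lengths[-1] == 0:
        lengths.pop()

    # positions: strictly increasing, ~exponential spacing
    gaps = 1 + rng.exponential(spec.spacing_mean, size=spec.n_snps).astype(np.int64)
    positions = np.cumsum(gaps) + 1

    matrix = np.empty((spec.n_haplotypes, spec.n_snps), dtype=np.uint8)
    j = 0
    for blen in lengths:
        founder_of = rng.integers(0, spec.n_founders, size=spec.n_haplotypes)
        for b in range(blen):
            if b > 0 and spec.mosaic_rate > 0:
                switch = rng.random(spec.n_haplotypes) < spec.mosaic_rate
                founder_of = np.where(
                    switch,
                    rng.integers(0, spec.n_founders, size=spec.n_haplotypes),
                    founder_of,
                )
            matrix[:, j] = _draw_column(rng, founder_of, spec.n_founders, spec.maf_min)
            j += 1

    # planted perfect-LD pairs: copy a column onto its right neighbour
    if spec.n_equivalent_pairs:
        eligible = np.arange(0, spec.n_snps - 1, 2)
        picks = rng.choice(eligible, size=min(spec.n_equivalent_pairs, len(eligible)),
                           replace=False)
        for i in sorted(int(p) for p in picks):
            matrix[:, i + 1] = matrix[:, i]

    ids = [f"snp{j:04d}" for j in range(spec.n_snps)]
    pairs = []
    for _ in range(spec.n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        pairs.append((_BASES[a], _BASES[b]))
    return panel_from_alleles(ids, positions, pairs, matrix)


def plant_rule(
    panel: HaplotypePanel,
    k: int,
    target: int,
    lhs: list[int] | None = None,
    noise: float = 0.0,
    function: str = "lookup",
    maf_min: float = 0.05,
    seed: int = 0,
) -> HaplotypePanel:
    """Overwrite ``target``'s column as a function of k other columns.

    ``lhs`` defaults to the k nearest SNPs by position.  ``function`` is
    "lookup" (a random non-constant map from observed LHS haplotypes to
    alleles, redrawn while the planted column violates ``maf_min``) or
    "parity" (XOR of the LHS codes).  ``noise`` flips each haplotype's
    planted allele independently.  At noise 0 the planted rule has
    co-occurrence r² = 1.  The caller must keep the span of lhs ∪ {target}
    within the max_dist of any downstream rule generation, or the planted
    rule is (correctly) rejected on distance grounds.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_haplotypes
    if lhs is None:
        order = sorted(
            (i for i in range(panel.n_snps) if i != target),
            key=lambda i: abs(int(panel.positions[i]) - int(panel.positions[target])),
        )
        lhs = sorted(order[:k])
    if len(lhs) != k or target in lhs:
        raise ValueError("lhs must hold k SNPs distinct from the target")

    sub = panel.matrix[:, lhs]
    keys = [tuple(int(v) for v in row) for row in sub]
    observed = sorted(set(keys))
    if function == "parity":
        values = {key: sum(key) % 2 for key in observed}
        col = np.array([values[key] for key in keys], dtype=np.uint8)
        if noise > 0:
            col ^= (rng.random(n) < noise).astype(np.uint8)
    else:
        col = None
        for _ in range(200):
            values = {key: int(rng.integers(0, 2)) for key in observed}
            if len(set(values.values())) < 2:
                continue
            cand = np.array([values[key] for key in keys], dtype=np.uint8)
            if noise > 0:
                cand = cand ^ (rng.random(n) < noise).astype(np.uint8)
            maf = min(cand.mean(), 1 - cand.mean())
            if maf >= maf_min:
                col = cand
                break
        if col is None:
            raise ValueError("cannot plant rule satisfying maf_min")

    matrix = panel.matrix.copy()
    matrix[:, target] = col
    ids = [s.id for s in panel.snps]
    positions = [s.position for s in panel.snps]
    pairs = [(s.major_allele, s.minor_allele) for s in panel.snps]
    return panel_from_alleles(ids, positions, pairs, matrix)
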