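"""Phased haplotype panel I/O.

A :class:`HaplotypePanel` is the single in-memory container every other
module works from: an ``n_haplotypes x n_snps`` matrix of 0/1 codes
(0 = major allele, 1 = minor allele) plus per-SNP metadata.  Panels are
read either from VCF (phased GT fields, via cyvcf2) or from a HapMap-style
pair of text files: a *legend* (SNP id, 1-based position, the two allele
symbols) and a whitespace-delimited haplotype matrix whose rows are
haplotypes and whose columns are SNPs, each cell 0 (legend allele0) or 1
(legend allele1).

Coding convention: the more frequent allele of each column is "major" and
is coded 0.  An exact 50/50 tie is broken toward the lexicographically
smaller allele symbol so that recoding is deterministic across runs and
populations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class PanelError(ValueError):
    """Malformed or unusable haplotype input."""


@dataclass(frozen=True)
class SNPRecord:
    """Metadata for one bi-allelic SNP.

    ``maf`` is the relative frequency of the minor allele among haplotypes
    (rows), always in [0, 0.5].
    """

    id: str
    position: int
    major_allele: str
    minor_allele: str
    maf: float


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a tagging run.

    min_r2
        r² threshold a rule must reach, in (0, 1].
    max_dist
        maximum base-pair distance between any two SNPs of a rule
        (inclusive comparison).
    max_size
        maximum number of SNPs on the left-hand side of a rule.
    maf_cutoff
        minor-allele-frequency filter (inclusive, SNPs with maf >= cutoff
        are kept).
    model
        "cooccurrence" or "one_vs_rest".
    skip_threshold
        once a SNP has appeared as the right-hand side of this many emitted
        rules it is no longer considered as a rule target; ``None`` disables
        the heuristic.
    rule_budget
        maximum number of rules held in memory at once; ``None`` means
        unlimited.  Finite budgets trigger chunked selection.
    """

    min_r2: float = 0.95
    max_dist: int = 100_000
    max_size: int = 3
    maf_cutoff: float = 0.05
    model: str = "cooccurrence"
    skip_threshold: int | None = None
    rule_budget: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_r2 <= 1.0):
            raise ValueError(f"min_r2 must be in (0, 1], got {self.min_r2}")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        if self.max_dist <= 0:
            raise ValueError("max_dist must be > 0")
        if self.model not in ("cooccurrence", "one_vs_rest"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.skip_threshold is not None and self.skip_threshold < 1:
            raise ValueError("skip_threshold must be >= 1 or None")


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix plus per-SNP metadata.

    ``matrix`` has shape (n_haplotypes, n_snps), dtype uint8, values in
    {0, 1} with 0 = major allele.  SNPs are ordered by strictly increasing
    position.
    """

    snps: list[SNPRecord]
    matrix: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snps):
            raise PanelError("matrix shape does not match SNP list")
        if self.matrix.shape[0] < 2:
            raise PanelError("a panel needs at least 2 haplotypes")
        pos = self.positions
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise PanelError("SNP positions must strictly increase")
        self._index = {s.id: i for i, s in enumerate(self.snps)}
        if len(self._index) != len(self.snps):
            raise PanelError("duplicate SNP ids")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.position for s in self.snps], dtype=np.int64)

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    def symbol(self, snp_index: int, code: int) -> str:
        s = self.snps[snp_index]
        return s.major_allele if code == 0 else s.minor_allele

    def column(self, snp_index: int) -> np.ndarray:
        return self.matrix[:, snp_index]

    def subset(self, keep: Sequence[int]) -> "HaplotypePanel":
        keep = list(keep)
        return HaplotypePanel([self.snps[i] for i in keep], self.matrix[:, keep])


def panel_from_alleles(
    ids: Sequence[str],
    positions: Sequence[int],
    allele_pairs: Sequence[tuple[str, str]],
    codes: np.ndarray,
) -> HaplotypePanel:
    """Build a panel from raw 0/1 codes referring to ``allele_pairs``.

    ``codes[h, j] == 0`` means haplotype h carries ``allele_pairs[j][0]``.
    Columns are recoded so 0 is the major allele; ties (exact 0.5) make the
    lexicographically smaller symbol major.  Recoding an already
    major-coded matrix is the identity.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    n_hap, n_snp = codes.shape
    snps: list[SNPRecord] = []
    matrix = codes.copy()
    for j in range(n_snp):
        a0, a1 = allele_pairs[j]
        if a0 == a1:
            raise PanelError(f"column {j} ({ids[j]}): alleles must differ")
        ones = int(matrix[:, j].sum())
        if 2 * ones > n_hap or (2 * ones == n_hap and a1 < a0):
            matrix[:, j] = 1 - matrix[:, j]
            a0, a1 = a1, a0
            ones = n_hap - ones
        # minor count divided fresh so maf == recomputed column frequency
        snps.append(SNPRecord(str(ids[j]), int(positions[j]), a0, a1, ones / n_hap))
    order = sorted(range(n_snp), key=lambda j: snps[j].position)
    if order != list(range(n_snp)):
        snps = [snps[j] for j in order]
        matrix = matrix[:, order]
    return HaplotypePanel(snps, matrix)


def read_legend_panel(
    legend_path: str | Path, hap_path: str | Path, strict: bool = False
) -> HaplotypePanel:
    """Read a legend file plus haplotype matrix into a panel.

    Legend columns: id, position, allele0, allele1 (whitespace-delimited;
    a non-numeric second field on the first line is treated as a header).
    With ``strict=True`` monomorphic columns are rejected immediately;
    otherwise they are kept (maf 0) and fall to the MAF filter later.
    """
    legend_lines = Path(legend_path).read_text().strip().splitlines()
    rows = []
    for ln, line in enumerate(legend_lines, 1):
        parts = line.split()
        if not parts:
            continue
        if ln == 1 and len(parts) >= 2 and not parts[1].lstrip("-").isdigit():
            continue  # header
        if len(parts) < 4:
            raise PanelError(f"legend line {ln}: expected 4 columns")
        rows.append((parts[0], int(parts[1]), parts[2], parts[3]))
    if not rows:
        raise PanelError("no SNPs in legend")

    hap_lines = [l for l in Path(hap_path).read_text().strip().splitlines() if l.strip()]
    if not hap_lines:
        raise PanelError("no haplotypes")
    codes = []
    for ln, line in enumerate(hap_lines, 1):
        vals = line.split()
        if len(vals) != len(rows):
            raise PanelError(
                f"haplotype row {ln}: {len(vals)} columns, legend has {len(rows)}"
            )
        try:
            row = [int(v) for v in vals]
        except ValueError as e:
            raise PanelError(f"haplotype row {ln}: non-integer cell") from e
        codes.append(row)
    codes = np.asarray(codes, dtype=np.int64)
    bad = np.where((codes < 0) | (codes > 1))
    if bad[0].size:
        raise PanelError(
            f"column {bad[1][0]}: more than two alleles (code {codes[bad][0]})"
        )
    if strict:
        for j in range(codes.shape[1]):
            if len(np.unique(codes[:, j])) < 2:
                raise PanelError(f"column {j} ({rows[j][0]}) is monomorphic")
    ids = [r[0] for r in rows]
    positions = [r[1] for r in rows]
    pairs = [(r[2], r[3]) for r in rows]
    return panel_from_alleles(ids, positions, pairs, codes.astype(np.uint8))


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def read_vcf_panel(vcf_path: str | Path, region: str | None = None) -> HaplotypePanel:
    """Read phased, bi-allelic records from a VCF into a panel.

    Every sample contributes two haplotype rows.  Unphased or missing GT
    fields are rejected (no imputation).  ``region`` is "chrom" or
    "chrom:start-end" (1-based inclusive), filtered during iteration so
    no index is required.
    """
    from cyvcf2 import VCF

    chrom = start = end = None
    if region is not None:
        m = _REGION_RE.match(region)
        if not m:
            raise PanelError(f"bad region {region!r}")
        chrom = m.group(1)
        if m.group(2):
            start, end = int(m.group(2)), int(m.group(3))

    vcf = VCF(str(vcf_path))
    ids, positions, pairs, cols = [], [], [], []
    for var in vcf:
        if chrom is not None and var.CHROM != chrom:
            continue
        if start is not None and not (start <= var.POS <= end):
            continue
        if len(var.ALT) != 1:
            raise PanelError(
                f"record {var.CHROM}:{var.POS} is not bi-allelic (ALT={var.ALT})"
            )
        col = []
        for g in var.genotypes:
            a0, a1, phased = g[0], g[1], g[2]
            if a0 < 0 or a1 < 0:
                raise PanelError(f"record {var.CHROM}:{var.POS}: missing genotype")
            if not phased:
                raise PanelError(f"record {var.CHROM}:{var.POS}: unphased genotype")
            col.extend((a0, a1))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        pairs.append((var.REF, var.ALT[0]))
        cols.append(col)
    vcf.close()
    if not cols:
        raise PanelError("no SNPs")
    codes = np.asarray(cols, dtype=np.uint8).T  # haplotypes x snps
    return panel_from_alleles(ids, positions, pairs, codes)


def filter_by_maf(panel: HaplotypePanel, maf_cutoff: float) -> HaplotypePanel:
    """Keep SNPs with maf >= cutoff (inclusive); order preserved, idempotent."""
    keep = [i for i, s in enumerate(panel.snps) if s.maf >= maf_cutoff]
    if not keep:
        raise PanelError(f"no SNPs pass MAF >= {maf_cutoff}")
    if len(keep) == panel.n_snps:
        return panel
    return panel.subset(keep)


def write_panel(
    panel: HaplotypePanel, legend_path: str | Path, hap_path: str | Path
) -> None:
    """Write a panel as legend + haplotype matrix (round-trips through
    :func:`read_legend_panel`; allele0 is written as the major allele)."""
    with open(legend_path, "w") as f:
        f.write("id position allele0 allele1\n")
        for s in panel.snps:
            f.write(f"{s.id} {s.position} {s.major_allele} {s.minor_allele}\n")
    with open(hap_path, "w") as f:
        for row in panel.matrix:
            f.write(" ".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Rule and tag-set serialization


RULES_HEADER = "lhs\trhs\tmodel\tr2\tmapping"


def _serialize_mapping(mapping: Mapping[tuple[str, ...], str]) -> str:
    items = sorted(mapping.items())
    return ";".join(",".join(k) + ">" + v for k, v in items)


def _parse_mapping(text: str) -> dict[tuple[str, ...], str]:
    mapping: dict[tuple[str, ...], str] = {}
    if not text:
        return mapping
    for entry in text.split(";"):
        key, _, val = entry.partition(">")
        mapping[tuple(key.split(","))] = val
    return mapping


def write_rules(rules: Iterable, path: str | Path) -> None:
    """Write tagging rules as a TSV: lhs ids (comma-joined), rhs id, model,
    r² (full precision), serialized haplotype→allele mapping."""
    with open(path, "w") as f:
        f.write(RULES_HEADER + "\n")
        for r in rules:
            f.write(
                "\t".join(
                    (
                        ",".join(r.lhs),
                        r.rhs,
                        r.model,
                        repr(float(r.r2)),
                        _serialize_mapping(r.mapping),
                    )
                )
                + "\n"
            )


def read_rules(path: str | Path) -> list:
    """Read rules written by :func:`write_rules` (round-trip identity)."""
    from .rule_engine import TaggingRule

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != RULES_HEADER:
        raise PanelError("rules file: missing or malformed header")
    rules = []
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise PanelError(f"rules file line {ln}: expected 5 columns")
        lhs, rhs, model, r2_text, map_text = parts
        try:
            r2 = float(r2_text)
        except ValueError as e:
            raise PanelError(f"rules file line {ln}: bad r2 {r2_text!r}") from e
        rules.append(
            TaggingRule(tuple(lhs.split(",")), rhs, model, r2, _parse_mapping(map_text))
        )
    return rules


def write_tag_set(state, panel: HaplotypePanel, path: str | Path) -> None:
    """Write the selected tag set: id, position, mandatory flag, chunk index."""
    with open(path, "w") as f:
        f.write("id\tposition\tmandatory\tchunk\n")
        for t in state.tags:
            pos = panel.snps[panel.index_of(t)].position
            mand = int(t in state.mandatory)
            f.write(f"{t}\t{pos}\t{mand}\t{state.chunk_of.get(t, 0)}\n")
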