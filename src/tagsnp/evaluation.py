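"""Cross-population rule evaluation (portability analysis).

Rules generated from one panel are applied to another: the haplotype→
allele mapping frozen at training time predicts the target allele of each
test haplotype, and the r² of the frozen grouping is recomputed from the
test panel's frequencies.  Alleles are matched across panels by symbol,
never by 0/1 code, since the major/minor orientation can flip between
populations.  Prediction accuracy of a rule is the proportion of target
alleles correctly predicted from the left-hand-side alleles.

A test haplotype whose LHS pattern was never observed in training has no
frozen prediction; it falls back to the test panel's major allele of the
target SNP and is counted in ``n_unseen`` (for the r² recomputation such
patterns join the group of the fallback allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .haplotype_io import HaplotypePanel
from .ld_models import _eq1_counts
from .rule_engine import TaggingRule


@dataclass
class RuleEvaluation:
    rule: TaggingRule
    r2_test: float
    accuracy: float
    n_unseen: int
    portable: bool = True


def evaluate_rule(
    rule: TaggingRule,
    test_panel: HaplotypePanel,
    id_map: dict[str, str] | None = None,
) -> RuleEvaluation:
    """Frozen-mapping evaluation of one rule on a test panel.

    ``id_map`` translates training SNP ids to test ids (identity by
    default).  A rule whose SNPs or allele symbols are absent from the
    test panel is returned with ``portable=False``.
    """
    id_map = id_map or {}

    def resolve(snp_id: str) -> int | None:
        tid = id_map.get(snp_id, snp_id)
        try:
            return test_panel.index_of(tid)
        except KeyError:
            return None

    lhs_idx = [resolve(i) for i in rule.lhs]
    rhs_idx = resolve(rule.rhs)
    if rhs_idx is None or any(i is None for i in lhs_idx):
        return RuleEvaluation(rule, float("nan"), float("nan"), 0, portable=False)

    rhs = test_panel.snps[rhs_idx]
    rule_symbols = set(rule.mapping.values())
    if rule_symbols and not rule_symbols <= {rhs.major_allele, rhs.minor_allele}:
        return RuleEvaluation(rule, float("nan"), float("nan"), 0, portable=False)

    n = test_panel.n_haplotypes
    lhs_sym = [
        (test_panel.snps[i].major_allele, test_panel.snps[i].minor_allele)
        for i in lhs_idx
    ]
    fallback = rhs.major_allele

    n_correct = 0
    n_unseen = 0
    # counts for the frozen grouping on the test panel, keyed by predicted
    # symbol: group_A = patterns predicting the training-mapped symbol
    pattern_counts: dict[tuple[str, ...], list[int]] = {}
    for h in range(n):
        key = tuple(lhs_sym[k][test_panel.matrix[h, i]] for k, i in enumerate(lhs_idx))
        actual = rhs.major_allele if test_panel.matrix[h, rhs_idx] == 0 else rhs.minor_allele
        pred = rule.mapping.get(key)
        if pred is None:
            pred = fallback
            n_unseen += 1
        if pred == actual:
            n_correct += 1
        cnt = pattern_counts.setdefault(key, [0, 0])
        cnt[0 if actual == rhs.major_allele else 1] += 1

    # frozen grouping: patterns predicted as the test-major symbol form H_A
    c_A = sum(c[0] for c in pattern_counts.values())
    c_HA = 0
    c_HAA = 0
    for key, (cA, ca) in pattern_counts.items():
        pred = rule.mapping.get(key, fallback)
        if pred == rhs.major_allele:
            c_HA += cA + ca
            c_HAA += cA
    r2_test = _eq1_counts(n, c_HA, c_A, c_HAA)
    return RuleEvaluation(rule, r2_test, n_correct / n, n_unseen)


def portability_report(
    rules,
    test_panel: HaplotypePanel,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per (rule length, model) summary of frozen-rule performance.

    Columns: rule count, mean test r², mean prediction accuracy, fraction
    of rules with accuracy >= 0.9, mean unseen-pattern count, and the
    number of non-portable rules excluded.
    """
    rows = []
    excluded: dict[tuple[int, str], int] = {}
    for rule in rules:
        ev = evaluate_rule(rule, test_panel, id_map)
        key = (len(rule.lhs), rule.model)
        if not ev.portable:
            excluded[key] = excluded.get(key, 0) + 1
            continue
        rows.append(
            {
                "length": key[0],
                "model": key[1],
                "r2_test": ev.r2_test,
                "accuracy": ev.accuracy,
                "n_unseen": ev.n_unseen,
            }
        )
    if not rows:
        raise ValueError("no evaluable rules")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["length", "model"])
        .agg(
            n_rules=("accuracy", "size"),
            mean_r2=("r2_test", "mean"),
            mean_accuracy=("accuracy", "mean"),
            frac_acc_ge_090=("accuracy", lambda a: float((a >= 0.9).mean())),
            mean_unseen=("n_unseen", "mean"),
        )
        .reset_index()
    )
    out["n_excluded"] = [
        excluded.get((l, m), 0) for l, m in zip(out["length"], out["model"])
    ]
    return out
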