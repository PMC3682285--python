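"""Downstream subtype comparisons: clinical attributes, pharmacogene fold
changes, and gene-set over-representation.

Binary clinical attributes are compared by two-sided Fisher's exact test,
continuous ones by the pooled-variance two-sample t-test (Welch by flag).
Fold changes are 2^(mean log2 subtype 1 - mean log2 subtype 2), so a
value above 1 means higher expression in subtype 1.  Over-representation
uses the upper-tail hypergeometric test with Bonferroni correction over
the number of sets tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, require_complete
from .sam import SamResult

__all__ = ["compare_clinical", "fold_changes", "overrepresentation"]

log = logging.getLogger(__name__)


def compare_clinical(clinical: ClinicalTable, labels: np.ndarray, welch: bool = False) -> pd.DataFrame:
    """Per-attribute subtype comparison in the style of a cohort table.

    Binary attributes report per-subtype percentages and a two-sided
    Fisher exact p; continuous attributes report per-subtype means and a
    two-sided Student's t (pooled variance, or Welch when ``welch``).
    An attribute with a single level overall gets p = 1 and a note.
    """
    labels = np.asarray(labels)
    if len(labels) != len(clinical.sample_ids):
        raise ParameterError("labels must cover every sample in the clinical table")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ParameterError("clinical comparison needs exactly 2 subtypes")
    in1, in2 = labels == groups[0], labels == groups[1]

    rows = []
    for attr in clinical.attributes:
        col = clinical.data[attr]
        x1 = col[in1].dropna().to_numpy()
        x2 = col[in2].dropna().to_numpy()
        if clinical.is_binary(attr):
            a, b = int(np.sum(x1 == 1)), int(np.sum(x1 == 0))
            c, d = int(np.sum(x2 == 1)), int(np.sum(x2 == 0))
            note = ""
            if (a + c == 0) or (b + d == 0):
                p = 1.0
                note = "single level overall"
            else:
                _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"attribute": attr, "type": "binary",
                 "subtype_1": 100.0 * a / max(a + b, 1), "subtype_2": 100.0 * c / max(c + d, 1),
                 "p_value": float(p), "test": "fisher_exact", "note": note}
            )
        else:
            if len(np.unique(np.concatenate([x1, x2]))) < 2:
                p, note = 1.0, "single level overall"
            else:
                _, p = stats.ttest_ind(x1, x2, equal_var=not welch)
                note = ""
            rows.append(
                {"attribute": attr, "type": "continuous",
                 "subtype_1": float(np.mean(x1)), "subtype_2": float(np.mean(x2)),
                 "p_value": float(p), "test": "welch_t" if welch else "student_t", "note": note}
            )
    return pd.DataFrame(rows)


def fold_changes(
    m: ExpressionMatrix,
    labels: np.ndarray,
    genes: list[str],
    sam_result: SamResult | None = None,
) -> pd.DataFrame:
    """Subtype-1-over-subtype-2 fold changes for the listed genes.

    FC = 2^(mean log2 in subtype 1 - mean log2 in subtype 2).  Genes
    absent from the platform are skipped and logged.  When a SamResult is
    supplied its per-gene q-value is attached so callers can report only
    the statistically supported differences.
    """
    require_complete(m, "fold_changes")
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ParameterError("fold_changes needs exactly 2 subtypes")
    present = set(m.gene_ids)
    found = [g for g in genes if g in present]
    skipped = [g for g in genes if g not in present]
    if skipped:
        log.warning("fold_changes: %d genes not on platform: %s", len(skipped), skipped[:10])
    if not found:
        raise DegenerateInputError("none of the requested genes are on the platform")
    sub = m.subset_genes(found)
    m1 = sub.values[:, labels == groups[0]].mean(axis=1)
    m2 = sub.values[:, labels == groups[1]].mean(axis=1)
    fc = 2.0 ** (m1 - m2)
    out = pd.DataFrame({"gene_id": found, "log2_diff": m1 - m2, "fold_change": fc})
    if sam_result is not None:
        qmap = dict(zip(sam_result.gene_ids, sam_result.q_values))
        out["q_value"] = [qmap.get(g, np.nan) for g in found]
    out.attrs["skipped_genes"] = skipped
    return out


def overrepresentation(
    signature: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the signature.

    Population = universe, successes = set members in the universe, draws
    = signature members in the universe; raw p = P(X >= overlap) upper
    tail; Bonferroni multiplies by the number of sets tested, capped at 1.
    Rows are sorted by raw p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise DegenerateInputError("empty universe")
    sig = [g for g in dict.fromkeys(signature) if g in universe_set]
    dropped = len(set(signature)) - len(sig)
    if dropped:
        log.warning("overrepresentation: dropped %d signature genes outside the universe", dropped)
    N, n_draw = len(universe_set), len(sig)
    m_tests = len(sets)
    rows = []
    for name, members in sets.items():
        K = len(set(members) & universe_set)
        overlap = len(set(members) & set(sig))
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n_draw)) if K else 1.0
        rows.append(
            {"set_name": name, "overlap": overlap, "set_size": K,
             "signature_size": n_draw, "universe_size": N,
             "p_value": min(p, 1.0), "bonferroni": min(1.0, p * m_tests)}
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
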