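"""Annotation joins: enriched/underrepresented sets, RBD classes, term fractions.

Nonclassical RNA-binding domains are classified from the distribution of
their member proteins' RIC/WCE ratios: "classical_like" domains sit high
(the proteins behave like professional RBPs), "substoichiometric" domains
sit low (only a small fraction of the protein pool is RNA-bound), and
"adaptive" domains span the full range.  Domains seen on fewer than
``min_proteins`` detected proteins stay unclassified.  Proteins that also
carry a classical RBD, and proteins annotated as cytosolic-ribosome
components, are excluded from the domain statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import POPULATION_BOTH, POPULATION_RIC_ONLY, AnnotationTable

KLASS_CLASSICAL_LIKE = "classical_like"
KLASS_SUBSTOICHIOMETRIC = "substoichiometric"
KLASS_ADAPTIVE = "adaptive"
KLASS_UNCLASSIFIED = "unclassified"

DOMAIN_CLASS_COLUMNS = [
    "pfam_id",
    "n_proteins_detected",
    "median_ratio",
    "iqr_ratio",
    "klass",
]


@dataclass(frozen=True)
class DomainClassConfig:
    min_proteins: int = 4
    hi: float = 2.0  # log2; the >4-fold enrichment cutoff
    lo: float = -2.0  # log2; the <0.25-fold underrepresentation cutoff
    exclude_go_term: str = "GO:0022626"  # cytosolic ribosome


@dataclass(frozen=True)
class SetComparison:
    term: str
    frac_in_set: float
    frac_in_reference: float
    k_set: int
    n_set: int
    k_ref: int
    n_ref: int


def select_sets(
    rows: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = -2.0,
    p_max: float = 0.01,
) -> tuple[list[str], list[str]]:
    """High-activity and underrepresented protein sets from enrichment rows.

    enriched: mean_log2fc > fc_hi (ratio > 4) and p < p_max;
    underrepresented: mean_log2fc < fc_lo (ratio < 0.25) and p < p_max.
    """
    enriched = rows.loc[
        (rows["mean_log2fc"] > fc_hi) & (rows["p"] < p_max), "protein_id"
    ].tolist()
    under = rows.loc[
        (rows["mean_log2fc"] < fc_lo) & (rows["p"] < p_max), "protein_id"
    ].tolist()
    return enriched, under


def _ric_detected(rows: pd.DataFrame) -> pd.DataFrame:
    return rows[rows["population"].isin([POPULATION_BOTH, POPULATION_RIC_ONLY])]


def classify_domains(
    rows: pd.DataFrame,
    annotations: AnnotationTable,
    config: DomainClassConfig = DomainClassConfig(),
) -> pd.DataFrame:
    """Assign each detected nonclassical domain exactly one RBD class.

    Decision order per domain, over eligible member ratios:
    unclassified if fewer than min_proteins members; classical_like if the
    median ratio >= hi; substoichiometric if the median <= lo; adaptive if
    the members span both thresholds; otherwise adaptive when the IQR
    exceeds (hi - lo)/2, else the nearest-median class.
    """
    detected = _ric_detected(rows)
    ratios = detected.set_index("protein_id")["mean_log2fc"]

    members: dict[str, list[float]] = {}
    for pid, ratio in ratios.items():
        if pid not in annotations.pfam:
            continue
        if annotations.has_classical_rbd(pid):
            continue
        if annotations.has_go_term(pid, config.exclude_go_term):
            continue
        for dom in annotations.nonclassical_domains(pid):
            members.setdefault(dom, []).append(float(ratio))

    out = []
    for dom in sorted(members):
        vals = np.asarray(members[dom])
        n = len(vals)
        med = float(np.median(vals))
        q75, q25 = np.percentile(vals, [75, 25])
        iqr = float(q75 - q25)
        if n < config.min_proteins:
            klass = KLASS_UNCLASSIFIED
        elif med >= config.hi:
            klass = KLASS_CLASSICAL_LIKE
        elif med <= config.lo:
            klass = KLASS_SUBSTOICHIOMETRIC
        elif vals.min() <= config.lo and vals.max() >= config.hi:
            klass = KLASS_ADAPTIVE
        elif iqr > (config.hi - config.lo) / 2.0:
            klass = KLASS_ADAPTIVE
        else:
            klass = KLASS_CLASSICAL_LIKE if med > 0 else KLASS_SUBSTOICHIOMETRIC
        out.append(
            {
                "pfam_id": dom,
                "n_proteins_detected": n,
                "median_ratio": med,
                "iqr_ratio": iqr,
                "klass": klass,
            }
        )
    return pd.DataFrame(out, columns=DOMAIN_CLASS_COLUMNS)


def term_fractions(
    set_ids,
    reference_ids,
    term: str,
    annotations: AnnotationTable,
) -> SetComparison:
    """Fraction of each set annotated with a GO term (descriptive, no test)."""
    set_ids = list(set_ids)
    reference_ids = list(reference_ids)
    if not set_ids or not reference_ids:
        raise ValueError("sets must be non-empty")
    k_set = sum(annotations.has_go_term(p, term) for p in set_ids)
    k_ref = sum(annotations.has_go_term(p, term) for p in reference_ids)
    return SetComparison(
        term=term,
        frac_in_set=k_set / len(set_ids),
        frac_in_reference=k_ref / len(reference_ids),
        k_set=k_set,
        n_set=len(set_ids),
        k_ref=k_ref,
        n_ref=len(reference_ids),
    )
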