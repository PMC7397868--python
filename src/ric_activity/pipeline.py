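"""End-to-end drivers composing the analysis stages.

These helpers fix the order of operations used throughout the analyses:
impute missing cells at the background floor within each batch, median-
center every column, merge batches, then compute statistics.
"""

from __future__ import annotations

import pandas as pd

from .comparative import CompareConfig, compare
from .enrichment import EnrichmentConfig, enrichment_table, prepare_table
from .tables import IntensityTable


def run_enrichment(
    table: IntensityTable,
    mode: str,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Impute (and, for WCE normalization, median-center), then score.

    mode="wce" uses median-normalized intensities; mode="nocl" uses raw
    (imputed-only) intensities, matching how the noCL-normalized
    interactome is computed from raw MS intensities.
    """
    prepared = prepare_table(
        table, impute_value=config.impute_value, normalize=(mode == "wce")
    )
    return enrichment_table(prepared, mode, config)


def prepare_pair(
    wt: IntensityTable,
    mut: IntensityTable,
    impute_value: float = 18.0,
) -> tuple[IntensityTable, IntensityTable]:
    """Align two raw tables on the protein union, impute, median-center."""
    union = list(wt.values.index)
    for p in mut.values.index:
        if p not in union:
            union.append(p)

    def expand(t: IntensityTable) -> IntensityTable:
        values = t.values.reindex(union)
        imputed = t.imputed.reindex(union, fill_value=False)
        return IntensityTable(values, t.samples, imputed)

    wt2 = prepare_table(expand(wt), impute_value=impute_value, normalize=True)
    mut2 = prepare_table(expand(mut), impute_value=impute_value, normalize=True)
    return wt2, mut2


def run_compare(
    wt_raw: IntensityTable,
    mut_raw: IntensityTable,
    config: CompareConfig = CompareConfig(),
    impute_value: float = 18.0,
) -> tuple[pd.DataFrame, float]:
    """Full comparative pipeline from raw tables to shift coefficients."""
    wt, mut = prepare_pair(wt_raw, mut_raw, impute_value=impute_value)
    return compare(wt, mut, config)
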