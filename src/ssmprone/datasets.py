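"""Worked-example inputs.

The per-exon counts of the published MLH1 splicing-reporter panel are small
enough to carry as printed numbers: 36 pathogenic exonic point mutations
across five internal exons, of which all six in exon 8 and five of seven in
exon 15 disrupted splicing, while exons 4, 5 and 7 yielded no splicing
disruption. The 23 mutations in the three negative exons are split as evenly
as possible (the published figure does not break them down per exon).

The per-variant table behind that panel (individual wild-type/mutant assay
read-outs and ESR score differences) is not redistributable and must be
supplied by the user as a TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: exon_id, mutations tested, mutations that disrupted splicing
MLH1_EXON_TALLIES = pd.DataFrame(
    [
        ("MLH1_exon4", 8, 0),
        ("MLH1_exon5", 8, 0),
        ("MLH1_exon7", 7, 0),
        ("MLH1_exon8", 6, 6),
        ("MLH1_exon15", 7, 5),
    ],
    columns=["exon_id", "n_tested", "n_esm"],
)


def mlh1_exon_tallies() -> pd.DataFrame:
    """Per-exon tested/disruptive mutation counts of the MLH1 panel."""
    return MLH1_EXON_TALLIES.copy()


def mlh1_mapsy_panel(path: str | Path | None = None) -> pd.DataFrame:
    """Load the per-variant MLH1 MaPSy panel from a user-supplied TSV.

    The table must carry one row per assayed variant with at least the
    columns ``variant_id``, ``esm`` (bool) and ``delta_esr``. This per-variant
    table is not redistributable, so no copy ships with the package; pass the
    path to your local copy.
    """
    if path is None:
        raise FileNotFoundError(
            "the per-variant MLH1 MaPSy panel is not redistributable and does "
            "not ship with this package; pass the path to a local TSV with "
            "columns variant_id, esm, delta_esr")
    df = pd.read_csv(path, sep="\t")
    missing = {"variant_id", "esm", "delta_esr"} - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    return df
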