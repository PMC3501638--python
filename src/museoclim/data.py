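"""Bundled reference data.

``published_genus_climate_means.csv`` transcribes published genus-level
summaries for 35 southern African rodent genera: locality and specimen
counts per genus, and the mean of each of the six bioclimatic variables
under both the locality (L) and the specimen (S) weighting. It serves as
the worked example for the cross-taxon summary statistics: the medians
and extremes reported for that dataset can be recomputed from these
columns alone.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .climate import VARIABLES


def load_genus_climate_means() -> pd.DataFrame:
    """Published per-genus climate means, wide: one row per genus.

    Columns: taxon, localities, specimens, then <VAR>_L and <VAR>_S for
    each of MAT, MxTWM, MnTCM (°C) and MAP, PWM, PDM (mm).
    """
    with resources.files(__package__).joinpath(
            "data/published_genus_climate_means.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def genus_means_to_stats(wide: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the wide genus table into tidy per-taxon mean statistics.

    Output columns (taxon, variable, weighting, mean) feed directly into
    :func:`museoclim.climate.cross_taxon_summary`.
    """
    if wide is None:
        wide = load_genus_climate_means()
    rows = []
    for _, r in wide.iterrows():
        for var in VARIABLES:
            for wt, suffix in (("LOCALITY", "L"), ("SPECIMEN", "S")):
                rows.append({"taxon": r["taxon"], "variable": var.value,
                             "weighting": wt, "mean": float(r[f"{var.value}_{suffix}"])})
    return pd.DataFrame(rows, columns=["taxon", "variable", "weighting", "mean"])
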