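"""Packaged per-row summary counts of the reference rice proteogenomics
study, with the derived-total arithmetic recomputed from the row values.

Three small CSVs ship with the package:

* ``msms_datasets.csv`` — per-dataset MS/MS counts (spectra, identified
  spectra at 1% FDR, identification rate, identified peptides, putative
  novel peptides);
* ``novel_locus_classes.csv`` — intergenic/intragenic counts for the novel
  peptide and cluster classes;
* ``results_scalars.csv`` — scalar counts quoted in the study's results.

:func:`summarize_reference_tables` recomputes every derivable total —
column sums, the global identification rate, and partition sums — from the
per-row component values only; printed totals are never read as input.
The peptide columns of the per-dataset table are distinct counts, not
additive, so their study-wide totals come from the known/novel partition
scalars instead of column sums.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ._util import percent_half_up


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("splicepept.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_msms_datasets() -> pd.DataFrame:
    return _load_csv("msms_datasets.csv")


def load_novel_locus_classes() -> pd.DataFrame:
    return _load_csv("novel_locus_classes.csv").set_index("row")


def load_results_scalars() -> dict[str, float]:
    df = _load_csv("results_scalars.csv")
    return dict(zip(df["name"], df["value"]))


def summarize_reference_tables() -> dict[str, float]:
    """Derived totals and rates from the packaged per-row values."""
    ds = load_msms_datasets()
    locus = load_novel_locus_classes()
    scalars = load_results_scalars()

    total_spectra = int(ds["spectra"].sum())
    total_identified = int(ds["identified_spectra"].sum())

    out: dict[str, float] = {
        "total_spectra": total_spectra,
        "total_identified_spectra": total_identified,
        "total_identification_rate_pct": percent_half_up(
            total_identified, total_spectra
        ),
        # peptide columns are distinct counts: totals from the partition
        "total_identified_peptides": int(
            scalars["known_peptides"] + scalars["putative_novel_peptides"]
        ),
        "junction_occurrences": int(
            scalars["known_junction_occurrences"]
            + scalars["novel_junction_occurrences"]
        ),
        "junction_sites": int(
            scalars["known_junction_sites"] + scalars["novel_junction_sites"]
        ),
        "assembled_transcripts": int(
            scalars["known_transcripts"] + scalars["novel_transcripts"]
        ),
    }
    for row in locus.index:
        out[f"{row}_total"] = int(
            locus.loc[row, "intergenic"] + locus.loc[row, "intragenic"]
        )
    out["clusters_with_fnps"] = out["nt_clusters_total"] + out["nj_clusters_total"]
    return out


def per_dataset_rates() -> pd.DataFrame:
    """Recompute each dataset's identification rate from its own counts."""
    ds = load_msms_datasets().copy()
    ds["recomputed_rate_pct"] = [
        percent_half_up(i, s) for i, s in zip(ds["identified_spectra"], ds["spectra"])
    ]
    return ds
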