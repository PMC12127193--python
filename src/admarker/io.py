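"""Plain-text I/O for the pipeline's standard tables."""

from __future__ import annotations

import pandas as pd

__all__ = [
    "write_clinical_csv",
    "read_clinical_csv",
    "write_proteome_tsv",
    "read_proteome_tsv",
]

_LATENT_PREFIX = "latent_"


def write_clinical_csv(cohort: pd.DataFrame, path) -> None:
    """One row per patient, ISO dates; generator-internal latent columns are
    never written."""
    out = cohort.loc[:, [c for c in cohort.columns if not c.startswith(_LATENT_PREFIX)]].copy()
    out["enrollment_date"] = pd.to_datetime(out["enrollment_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["enrollment_date"])
    required = {"patient_id", "arm", "easi_baseline", "easi_wk4", "iga_baseline", "iga_wk4"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def write_proteome_tsv(matrix: pd.DataFrame, path) -> None:
    """Rows = patients, columns = protein ids, values in fmol."""
    matrix.to_csv(path, sep="\t")


def read_proteome_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
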