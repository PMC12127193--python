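"""Transition-level QC filtering and absolute quantification for targeted MRM-MS.

Quantification follows the stable-isotope-dilution convention: a stable
isotope-labeled standard (SIS) peptide is spiked at a known amount, and the
endogenous amount is the peak-area ratio (PAR, endogenous/SIS) times the
spiked amount, in fmol.  QC removes transitions with weak SIS signal, SIS
peaks that do not co-elute with the endogenous peptide, or asymmetric elution
profiles, then requires a linear spike-level response with PAR inside (0.1, 1)
at every calibration level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSION_RULES",
    "LinearitySeries",
    "collision_energy",
    "filter_transitions",
    "quantify_fmol",
    "quantify_report",
    "linearity_pass",
    "dynamic_range_orders",
    "read_transition_csv",
]

#: Exclusion rules in reporting order; each excluded record is attributed to
#: the first rule it fails.
EXCLUSION_RULES = ("low_intensity", "not_coeluted", "asymmetric")

MIN_SIS_INTENSITY = 100.0
PAR_WINDOW = (0.1, 1.0)


def collision_energy(precursor_mz: float, charge: int) -> float:
    """Base collision energy (V) as a linear function of precursor m/z.

    Doubly charged precursors use CE = 0.031*mz + 1; triply charged use
    CE = 0.036*mz - 4.8.  Other charge states have no calibrated slope and
    raise rather than silently defaulting.
    """
    if precursor_mz <= 0:
        raise ValueError("precursor m/z must be positive")
    if charge == 2:
        return 0.031 * precursor_mz + 1.0
    if charge == 3:
        return 0.036 * precursor_mz - 4.8
    raise ValueError(f"no collision-energy calibration for charge {charge}")


def filter_transitions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three transition exclusion rules and tally exclusions.

    A record is kept iff sis_intensity >= 100 counts (the boundary value 100
    is kept: "below 100" excludes strictly smaller) AND it co-eluted AND its
    peak was symmetric.  The tally attributes each excluded record to the
    first failing rule in :data:`EXCLUSION_RULES` order.  Peak-shape and
    co-elution judgments are precomputed boolean flags in the report.
    """
    sis = records["sis_intensity"].to_numpy(dtype=float)
    coel = records["coeluted"].to_numpy().astype(bool)
    sym = records["symmetric"].to_numpy().astype(bool)

    low = sis < MIN_SIS_INTENSITY
    noco = ~low & ~coel
    asym = ~low & coel & ~sym
    keep = ~(low | noco | asym)

    tally = {
        "low_intensity": int(low.sum()),
        "not_coeluted": int(noco.sum()),
        "asymmetric": int(asym.sum()),
    }
    return records.loc[keep].copy(), tally


def quantify_fmol(par, sis_injected):
    """Endogenous amount (fmol) = PAR x SIS injected.  Vectorized."""
    par = np.asarray(par, dtype=float)
    sis = np.asarray(sis_injected, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    if np.any(sis <= 0):
        raise ValueError("SIS injected amount must be positive")
    out = par * sis
    return float(out) if out.ndim == 0 else out


def quantify_report(records: pd.DataFrame) -> pd.DataFrame:
    """QC-filter a transition report and attach absolute amounts.

    Returns the kept records with an added ``fmol`` column
    (= par * spike_fmol); the QC tally is attached as ``.attrs['qc_tally']``.
    """
    kept, tally = filter_transitions(records)
    kept = kept.copy()
    kept["fmol"] = quantify_fmol(kept["par"], kept["spike_fmol"])
    kept.attrs["qc_tally"] = tally
    return kept


@dataclass(frozen=True)
class LinearitySeries:
    """PAR measured at the four calibration spike levels for one peptide."""

    peptide_id: str
    levels: tuple[float, ...] = (50.0, 100.0, 200.0, 400.0)
    par_at_level: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.par_at_level):
            raise ValueError("levels and par_at_level must have equal length")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")


def linearity_pass(series: LinearitySeries, r2_min: float = 0.9) -> bool:
    """Spike-level linearity filter.

    Passes iff every PAR lies strictly inside (0.1, 1) and the squared
    Pearson correlation of PAR against spike level is at least ``r2_min``.
    The PAR window is absolute; the R^2 requirement is a configurable
    tightening of the qualitative linearity criterion.
    """
    if len(series.levels) != 4:
        raise ValueError("linearity series must cover all four spike levels")
    par = np.asarray(series.par_at_level, dtype=float)
    if np.any(par <= PAR_WINDOW[0]) or np.any(par >= PAR_WINDOW[1]):
        return False
    levels = np.asarray(series.levels, dtype=float)
    r = np.corrcoef(levels, par)[0, 1]
    return bool(r * r >= r2_min)


def linearity_table(linearity: pd.DataFrame, r2_min: float = 0.9) -> pd.DataFrame:
    """Evaluate :func:`linearity_pass` for every peptide in a long-form table."""
    rows = []
    for pep, grp in linearity.groupby("peptide_id", sort=True):
        grp = grp.sort_values("spike_fmol")
        series = LinearitySeries(
            peptide_id=pep,
            levels=tuple(grp["spike_fmol"]),
            par_at_level=tuple(grp["par"]),
        )
        rows.append({"peptide_id": pep, "passed": linearity_pass(series, r2_min)})
    return pd.DataFrame(rows)


def dynamic_range_orders(matrix: pd.DataFrame) -> tuple[float, pd.Series]:
    """Orders of magnitude spanned by the quant matrix.

    Returns ``(overall, per_protein)`` where overall = log10(max/min) over the
    positive per-protein medians and per_protein is the log10 spread of each
    protein across patients.  All-zero (or all non-positive) proteins are
    excluded with a warning.
    """
    medians = matrix.median(axis=0)
    bad = medians <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} protein(s) with non-positive median excluded "
            "from dynamic-range summary"
        )
        medians = medians[~bad]
    if medians.empty:
        raise ValueError("no protein with positive median abundance")
    overall = float(np.log10(medians.max() / medians.min()))

    pos = matrix.where(matrix > 0)
    per_protein = np.log10(pos.max(axis=0) / pos.min(axis=0))
    return overall, per_protein


def read_transition_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a Skyline-style transition CSV, renaming columns via ``column_map``.

    ``column_map`` maps source column names to the canonical names
    (peptide_id, protein_id, sis_intensity, endo_intensity, coeluted,
    symmetric, spike_fmol, par).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"peptide_id", "protein_id", "sis_intensity", "coeluted", "symmetric", "par"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transition report missing columns: {sorted(missing)}")
    return df
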