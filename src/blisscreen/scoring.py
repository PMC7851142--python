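"""Relative cell numbers and the two interaction metrics, Δ and CDI.

Raw nuclei counts are first normalised within each plate to that plate's
non-targeting-control (siControl) reference, then drug-arm values are
rescaled by the drug-effect factor so that every relative cell number shares
a single reference: siControl + vehicle == 1.  In that frame the screen's
two per-reagent metrics are

    Δ   = r(siRNA+vehicle) − r(siRNA+drug)
    CDI = r(siRNA+drug) / (r(siRNA+vehicle) × r(siControl+drug))

CDI is the observed combined survival over the Bliss-independence product of
the single-perturbation survivals: < 1 synergy, 1 independence, > 1
antagonism.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    DomainError,
    MissingReferenceError,
)
from .screen_data import ScreenDesign, WellRecord, wells_to_frame

GENE_SCORE_COLUMNS = (
    "reagent_id",
    "gene_symbol",
    "reagent_class",
    "r_sirna_vehicle",
    "r_sirna_drug",
    "r_control_drug",
    "delta",
    "cdi",
    "cdi_defined",
)


def interaction_difference(r_sirna_vehicle: float, r_sirna_drug: float) -> float:
    """Δ: how many more (relative) cells the drug removes from this knockdown.

    Positive when the knockdown sensitises to the drug; negative in the
    antagonistic direction (never a hit).
    """
    if not (np.isfinite(r_sirna_vehicle) and np.isfinite(r_sirna_drug)):
        raise DomainError("relative cell numbers must be finite")
    if r_sirna_vehicle < 0 or r_sirna_drug < 0:
        raise DomainError("relative cell numbers must be >= 0")
    return r_sirna_vehicle - r_sirna_drug


def cdi(r_sirna_drug: float, r_sirna_vehicle: float, r_control_drug: float) -> float:
    """Coefficient of drug interaction under the Bliss independence model.

    Returns NaN (the undefined flag, never a pseudo-number) when the
    denominator is zero; raises :class:`DomainError` on negative input.
    """
    for v in (r_sirna_drug, r_sirna_vehicle, r_control_drug):
        if v < 0:
            raise DomainError(f"relative cell numbers must be >= 0, got {v}")
    denom = r_sirna_vehicle * r_control_drug
    if denom == 0:
        return math.nan
    return r_sirna_drug / denom


def plate_control_reference(
    plate_wells: Iterable[WellRecord],
    control_reagent_ids: frozenset[str] | set[str] | None = None,
) -> float:
    """Median control cell count of one plate — the normalisation reference.

    Control wells are those of class ``nontargeting_control`` or whose
    reagent_id is listed in ``control_reagent_ids``.
    """
    counts = [
        w.cell_count
        for w in plate_wells
        if w.reagent_class == "nontargeting_control"
        or (control_reagent_ids and w.reagent_id in control_reagent_ids)
    ]
    if not counts:
        raise MissingReferenceError("plate has no non-targeting control wells")
    ref = float(np.median(counts))
    if ref == 0:
        raise DegenerateReferenceError("all control wells on plate counted zero cells")
    return ref


def _control_drug_factor(
    vehicle_refs: Sequence[float], drug_refs: Sequence[float]
) -> float:
    """Cross-arm drug-effect factor r(siControl+drug) vs r(siControl+vehicle).

    Ratio of median plate references when either arm has <= 2 replicate
    plates, median of all pairwise drug/vehicle ratios otherwise; no plate
    pairing scheme is assumed.
    """
    if min(len(vehicle_refs), len(drug_refs)) <= 2:
        return float(np.median(drug_refs) / np.median(vehicle_refs))
    ratios = [d / v for d in drug_refs for v in vehicle_refs]
    return float(np.median(ratios))


def relative_cell_numbers(
    wells: Sequence[WellRecord],
    design: ScreenDesign,
    aggregator: str = "median",
) -> pd.DataFrame:
    """Per-reagent, per-arm relative cell numbers in the siControl+vehicle frame.

    Per plate, each well's count is divided by that plate's control
    reference; within-plate values are aggregated per reagent (median), then
    across replicate plates with ``aggregator`` ("median" default, "mean"
    optional).  Drug-arm values are then rescaled by the drug-effect factor
    so the vehicle-arm siControl maps to exactly 1 and the drug-arm
    siControl to r_control_drug.

    Returns a tidy DataFrame: reagent_id, gene_symbol, reagent_class,
    treatment, value, n_replicates, plus the scalar factor in attrs
    ``r_control_drug``.  Empty wells are excluded.
    """
    if aggregator not in ("median", "mean"):
        raise ValueError("aggregator must be 'median' or 'mean'")
    df = wells_to_frame(wells)
    df = df[df["reagent_class"] != "empty"].copy()

    is_ctrl = (df["reagent_class"] == "nontargeting_control") | df["reagent_id"].isin(
        design.control_reagent_ids
    )
    refs: dict[str, float] = {}
    plate_arm: dict[str, str] = {}
    for plate_id, sub in df.groupby("plate_id"):
        ctrl_counts = sub.loc[is_ctrl.loc[sub.index], "cell_count"]
        if ctrl_counts.empty:
            raise MissingReferenceError(f"no control wells on plate {plate_id}")
        ref = float(ctrl_counts.median())
        if ref == 0:
            raise DegenerateReferenceError(
                f"all control wells counted zero on plate {plate_id}"
            )
        refs[plate_id] = ref
        plate_arm[plate_id] = sub["treatment"].iloc[0]

    vehicle_refs = [r for p, r in refs.items() if plate_arm[p] == design.vehicle_arm]
    drug_refs = [r for p, r in refs.items() if plate_arm[p] == design.drug_arm]
    if not vehicle_refs or not drug_refs:
        raise MissingReferenceError("both treatment arms need at least one plate")
    r_control_drug = _control_drug_factor(vehicle_refs, drug_refs)

    df["ratio"] = df["cell_count"] / df["plate_id"].map(refs)
    # within-plate aggregation first (controls occupy many wells per plate),
    # then across replicate plates
    per_plate = (
        df.groupby(["reagent_id", "gene_symbol", "reagent_class", "treatment", "plate_id"])
        ["ratio"]
        .median()
        .reset_index()
    )
    agg_fn = "median" if aggregator == "median" else "mean"
    out = (
        per_plate.groupby(["reagent_id", "gene_symbol", "reagent_class", "treatment"])
        ["ratio"]
        .agg(value=agg_fn, n_replicates="count")
        .reset_index()
    )
    drug_mask = out["treatment"] == design.drug_arm
    out.loc[drug_mask, "value"] *= r_control_drug
    out.attrs["r_control_drug"] = r_control_drug
    return out


def score_screen(
    wells: Sequence[WellRecord],
    design: ScreenDesign,
    aggregator: str = "median",
    reagent_classes: tuple[str, ...] = ("pool", "duplex"),
) -> pd.DataFrame:
    """Compute per-reagent GeneScores (r values, Δ and CDI) from raw wells.

    One row per target reagent with columns
    ``reagent_id, gene_symbol, reagent_class, r_sirna_vehicle, r_sirna_drug,
    r_control_drug, delta, cdi, cdi_defined``.  CDI is NaN with
    ``cdi_defined == False`` when its denominator vanishes; such reagents
    are reported but never called as hits downstream.
    """
    rel = relative_cell_numbers(wells, design, aggregator=aggregator)
    r_control_drug = rel.attrs["r_control_drug"]
    targets = rel[rel["reagent_class"].isin(reagent_classes)]
    wide = targets.pivot_table(
        index=["reagent_id", "gene_symbol", "reagent_class"],
        columns="treatment",
        values="value",
        aggfunc="first",
    ).reset_index()
    veh, drg = design.vehicle_arm, design.drug_arm
    for arm in (veh, drg):
        if arm not in wide.columns:
            wide[arm] = np.nan
    rows = []
    for r in wide.itertuples(index=False):
        rv = getattr(r, veh)
        rd = getattr(r, drg)
        if pd.isna(rv) or pd.isna(rd):
            delta, c = math.nan, math.nan
        else:
            delta = interaction_difference(rv, rd)
            c = cdi(rd, rv, r_control_drug)
        rows.append(
            (r.reagent_id, r.gene_symbol, r.reagent_class, rv, rd,
             r_control_drug, delta, c, bool(np.isfinite(c)))
        )
    out = pd.DataFrame(rows, columns=list(GENE_SCORE_COLUMNS))
    out = out.sort_values(["gene_symbol", "reagent_id"], kind="stable").reset_index(drop=True)
    out.attrs["r_control_drug"] = r_control_drug
    return out
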