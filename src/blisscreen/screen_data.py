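"""Data model and I/O for arrayed-screen plate tables and drug checkerboards.

The central objects are :class:`WellRecord` (one well of a 384-well plate:
identity, reagent, treatment arm, raw nuclei count), :class:`ScreenDesign`
(the two-arm replicate-plate layout of the screen) and
:class:`CheckerboardGrid` (a replicate dose x dose viability matrix for a
two-drug combination assay).

Screen tables are plain delimited text (comma or tab, auto-detected) with
columns ``plate_id, well, reagent_id, gene_symbol, reagent_class, treatment,
cell_count``.  Checkerboards are one delimited file per replicate: first row
holds drug-B doses, first column drug-A doses, body the raw responses.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, RowValidationError, StructuralError

REAGENT_CLASSES = ("pool", "duplex", "nontargeting_control", "empty")
SCREEN_COLUMNS = (
    "plate_id",
    "well",
    "reagent_id",
    "gene_symbol",
    "reagent_class",
    "treatment",
    "cell_count",
)

_WELL_RE = re.compile(r"^([A-Pa-p])0?([1-9]|1[0-9]|2[0-4])$")


def parse_well(label: str) -> str:
    """Canonicalise a well coordinate to zero-padded form ("A1" -> "A01").

    Rows run A-P and columns 1-24 (384-well plate).  Raises ``ValueError``
    for anything outside that range, naming the offending part.
    """
    m = _WELL_RE.match(str(label).strip())
    if m is None:
        raise ValueError(
            f"well {label!r}: expected row letter A-P followed by column 1-24"
        )
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


@dataclass(frozen=True)
class WellRecord:
    """One well: plate, coordinate, reagent, treatment arm and raw cell count.

    ``cell_count`` is the DAPI-stained nuclei count for the imaged fields of
    the well, the raw observable behind every relative cell number.
    """

    plate_id: str
    well: str
    reagent_id: str
    gene_symbol: str
    reagent_class: str
    treatment: str
    cell_count: float

    def __post_init__(self):
        object.__setattr__(self, "well", parse_well(self.well))
        if self.reagent_class not in REAGENT_CLASSES:
            raise ValueError(
                f"reagent_class {self.reagent_class!r} not one of {REAGENT_CLASSES}"
            )
        if self.cell_count < 0:
            raise ValueError(f"cell_count must be >= 0, got {self.cell_count}")
        if self.reagent_class == "nontargeting_control" and self.gene_symbol:
            raise ValueError("nontargeting_control wells must have empty gene_symbol")


@dataclass(frozen=True)
class ScreenDesign:
    """Two-arm replicate-plate layout of an arrayed combination screen.

    Defaults mirror a four-replicate-plate screen split two plates per arm
    (vehicle vs drug), one SMARTpool of four duplexes per gene, and a single
    non-targeting control reagent used as the normalisation reference.
    """

    arms: tuple[str, str] = ("vehicle", "drug")
    replicates_per_arm: int = 2
    control_reagent_ids: frozenset[str] = frozenset({"siControl"})
    duplexes_per_gene: int = 4

    def __post_init__(self):
        object.__setattr__(
            self, "control_reagent_ids", frozenset(self.control_reagent_ids)
        )
        if self.replicates_per_arm < 1:
            raise ValueError("replicates_per_arm must be >= 1")
        if self.duplexes_per_gene < 1:
            raise ValueError("duplexes_per_gene must be >= 1")
        if not self.control_reagent_ids:
            raise ValueError("control_reagent_ids must be non-empty")
        if len(set(self.arms)) != 2:
            raise ValueError("exactly two distinct treatment arms are required")

    @property
    def vehicle_arm(self) -> str:
        return self.arms[0]

    @property
    def drug_arm(self) -> str:
        return self.arms[1]


@dataclass
class CheckerboardGrid:
    """Replicate dose-matrix responses for a two-drug checkerboard assay.

    ``responses`` has shape (n_reps, len(drug_a_doses), len(drug_b_doses));
    axis doses are strictly ascending and include the zero-dose anchor.
    """

    drug_a_doses: np.ndarray
    drug_b_doses: np.ndarray
    responses: np.ndarray
    drug_a_name: str = "drug_a"
    drug_b_name: str = "drug_b"

    def __post_init__(self):
        self.drug_a_doses = np.asarray(self.drug_a_doses, dtype=float)
        self.drug_b_doses = np.asarray(self.drug_b_doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 2:
            self.responses = self.responses[None, :, :]
        for name, doses in (("drug_a", self.drug_a_doses), ("drug_b", self.drug_b_doses)):
            if np.any(np.diff(doses) <= 0):
                raise StructuralError(f"{name} doses must be strictly ascending")
            if doses[0] != 0:
                raise StructuralError(
                    f"{name} doses must include the 0-dose anchor as first entry"
                )
        if self.responses.shape[1:] != (len(self.drug_a_doses), len(self.drug_b_doses)):
            raise StructuralError("response matrix shape does not match dose axes")
        if np.any(self.responses < 0):
            raise StructuralError("responses must be >= 0")

    @property
    def n_reps(self) -> int:
        return self.responses.shape[0]


@dataclass
class ValidationReport:
    """Per-plate summary plus design flags from :func:`validate_design`.

    ``flags`` is sorted and content-deterministic: shuffling the input wells
    changes nothing.  ``fatal`` flags (missing controls, inconsistent arms)
    should abort scoring; the report itself never raises.
    """

    plates: pd.DataFrame
    flags: list[str] = field(default_factory=list)
    fatal_flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal_flags


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    """Tabulate WellRecords into a DataFrame with the canonical columns."""
    return pd.DataFrame(
        [
            (w.plate_id, w.well, w.reagent_id, w.gene_symbol, w.reagent_class,
             w.treatment, w.cell_count)
            for w in wells
        ],
        columns=list(SCREEN_COLUMNS),
    )


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    return [
        WellRecord(
            plate_id=str(r.plate_id),
            well=str(r.well),
            reagent_id=str(r.reagent_id),
            gene_symbol="" if pd.isna(r.gene_symbol) else str(r.gene_symbol),
            reagent_class=str(r.reagent_class),
            treatment=str(r.treatment),
            cell_count=float(r.cell_count),
        )
        for r in df.itertuples(index=False)
    ]


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override:
        return override
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise FormatError(f"{path}: empty file")


def read_screen_table(
    path: str | Path,
    design: ScreenDesign | None = None,
    delimiter: str | None = None,
) -> list[WellRecord]:
    """Read a delimited screen table into WellRecords.

    Comment lines starting with ``#`` are skipped.  Any row that fails field
    parsing (bad well coordinate, negative count, unknown reagent class) is
    collected and reported with its 1-based file line number in a single
    :class:`RowValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    sep = _sniff_delimiter(path, delimiter)

    # Track physical line numbers: pandas cannot report them once comments
    # are stripped, so map row index -> file line up front.
    line_numbers: list[int] = []
    buf = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        header_line = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if header_line is None:
                header_line = lineno
            else:
                line_numbers.append(lineno)
            buf.write(line)
    buf.seek(0)
    df = pd.read_csv(buf, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    wells: list[WellRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            count = float(getattr(row, "cell_count"))
            wells.append(
                WellRecord(
                    plate_id=getattr(row, "plate_id"),
                    well=getattr(row, "well"),
                    reagent_id=getattr(row, "reagent_id"),
                    gene_symbol=getattr(row, "gene_symbol"),
                    reagent_class=getattr(row, "reagent_class"),
                    treatment=getattr(row, "treatment"),
                    cell_count=count,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line_numbers[i], str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:20])
        raise RowValidationError(
            f"{path}: {len(bad)} row(s) failed validation: {detail}",
            lines=[ln for ln, _ in bad],
        )
    return wells


def write_screen_table(
    wells: Iterable[WellRecord],
    path: str | Path,
    params: dict | None = None,
) -> None:
    """Write WellRecords as TSV with a commented provenance header."""
    write_table(wells_to_frame(wells), path, params)


def write_table(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV, preceded by ``#``-comment provenance lines.

    The header embeds the package version and the resolved parameters as
    JSON so any output file can be traced (and re-run) from its own header.
    Deliberately no timestamp: identical inputs give byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# blisscreen v{__version__}\n")
        if params:
            fh.write(f"# config: {json.dumps(params, sort_keys=True, default=str)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table` (comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_embedded_config(path: str | Path) -> dict:
    """Recover the ``# config:`` JSON header from a written table."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# config:"):
                return json.loads(line[len("# config:"):])
            if not line.startswith("#"):
                break
    return {}


def validate_design(
    wells: Sequence[WellRecord], design: ScreenDesign
) -> ValidationReport:
    """Check a well collection against the screen design; never raises.

    Reports, per plate: treatment arm, well and control counts, replicate
    index (order of appearance among same-arm plates, by sorted plate id).
    Fatal flags: a plate without any non-targeting control well, or a plate
    whose wells disagree on treatment (arm is a per-plate property).
    Non-fatal: genes present in only one arm.
    """
    if not wells:
        raise ValueError("empty well collection")
    df = wells_to_frame(wells)
    fatal: list[str] = []
    flags: list[str] = []

    rows = []
    for plate_id, sub in sorted(df.groupby("plate_id"), key=lambda kv: kv[0]):
        arms = sorted(sub["treatment"].unique())
        if len(arms) > 1:
            fatal.append(f"mixed treatment arms on plate: {plate_id} ({', '.join(arms)})")
        is_ctrl = (sub["reagent_class"] == "nontargeting_control") | sub[
            "reagent_id"
        ].isin(design.control_reagent_ids)
        n_ctrl = int(is_ctrl.sum())
        if n_ctrl == 0:
            fatal.append(f"no control wells: {plate_id}")
        rows.append((plate_id, arms[0], len(sub), n_ctrl))
    plates = pd.DataFrame(rows, columns=["plate_id", "treatment", "n_wells", "n_controls"])
    plates["replicate_index"] = plates.groupby("treatment").cumcount() + 1

    # genes present in only one arm can never be scored
    targets = df[df["reagent_class"].isin(("pool", "duplex")) & (df["gene_symbol"] != "")]
    if not targets.empty:
        arms_per_gene = targets.groupby("gene_symbol")["treatment"].nunique()
        for gene in sorted(arms_per_gene[arms_per_gene < 2].index):
            flags.append(f"single-arm gene: {gene}")

    missing_arms = set(design.arms) - set(plates["treatment"])
    for arm in sorted(missing_arms):
        fatal.append(f"no plates in arm: {arm}")

    return ValidationReport(plates=plates, flags=sorted(flags), fatal_flags=sorted(fatal))


def read_checkerboard(
    paths: Sequence[str | Path],
    delimiter: str | None = None,
    drug_a_name: str = "drug_a",
    drug_b_name: str = "drug_b",
) -> CheckerboardGrid:
    """Read one delimited dose-matrix file per replicate into a grid.

    Layout: first row = drug-B doses (first cell is a label and is ignored),
    first column = drug-A doses, body = raw responses.  All replicates must
    share identical dose axes, sorted ascending after reading, and the grid
    must contain the untreated (0, 0) anchor cell.
    """
    if not paths:
        raise StructuralError("at least one replicate file is required")
    mats, axes = [], []
    for p in paths:
        p = Path(p)
        sep = _sniff_delimiter(p, delimiter)
        df = pd.read_csv(p, sep=sep, index_col=0, comment="#")
        a = df.index.to_numpy(dtype=float)
        b = df.columns.to_numpy(dtype=float)
        order_a, order_b = np.argsort(a), np.argsort(b)
        mats.append(df.to_numpy(dtype=float)[np.ix_(order_a, order_b)])
        axes.append((a[order_a], b[order_b]))
    a0, b0 = axes[0]
    for i, (a, b) in enumerate(axes[1:], start=2):
        if len(a) != len(a0) or len(b) != len(b0) or not (
            np.allclose(a, a0) and np.allclose(b, b0)
        ):
            raise StructuralError(
                f"replicate file {i} ({paths[i-1]}) has dose axes differing from replicate 1"
            )
    if a0[0] != 0 or b0[0] != 0:
        raise StructuralError(
            "checkerboard must contain the (0, 0) untreated anchor cell "
            "(both dose axes must include 0)"
        )
    return CheckerboardGrid(
        drug_a_doses=a0,
        drug_b_doses=b0,
        responses=np.stack(mats),
        drug_a_name=drug_a_name,
        drug_b_name=drug_b_name,
    )


def write_checkerboard(grid: CheckerboardGrid, paths: Sequence[str | Path]) -> None:
    """Write one file per replicate in the layout read_checkerboard expects."""
    if len(paths) != grid.n_reps:
        raise ValueError("need exactly one output path per replicate")
    for rep, p in enumerate(paths):
        df = pd.DataFrame(
            grid.responses[rep], index=grid.drug_a_doses, columns=grid.drug_b_doses
        )
        df.index.name = "dose"
        Path(p).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, sep="\t")
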