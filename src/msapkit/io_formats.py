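"""Reading, writing and construction of MSAP band matrices.

MSAP (methylation-sensitive amplified polymorphism) fingerprints each
individual twice with isoschizomer digests — EcoRI/HpaII ("HPA") and
EcoRI/MspI ("MSP") — over a shared set of anonymous AFLP loci.  This module
handles the band-matrix CSV dialect (one row per individual x enzyme, 0/1
per locus), the sample sheet mapping individuals to populations, and the
binning of raw fragment-analysis peak tables (size in bp, height in RFU)
into binary band matrices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ENZYMES = ("HPA", "MSP")


class MsapError(Exception):
    """Base class for msapkit errors."""


class MsapFormatError(MsapError):
    """Malformed input file or inconsistent band-matrix structure."""


class EmptyAnalysisError(MsapError):
    """An analysis step was left with no usable loci or individuals."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakTable:
    """Fragment peaks for one individual under one enzyme digest.

    Parameters
    ----------
    individual_id : str
        Sample identifier.
    enzyme : str
        ``"HPA"`` (EcoRI/HpaII digest) or ``"MSP"`` (EcoRI/MspI digest).
    peaks : sequence of (size_bp, height_rfu)
        Fragment size in base pairs and peak height in relative
        fluorescence units; both strictly positive.
    """

    individual_id: str
    enzyme: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        enzyme = self.enzyme.upper()
        if enzyme not in ENZYMES:
            raise MsapFormatError(
                f"unknown enzyme tag {self.enzyme!r} for individual "
                f"{self.individual_id!r}; expected one of {ENZYMES}"
            )
        object.__setattr__(self, "enzyme", enzyme)
        object.__setattr__(self, "peaks", tuple((float(s), float(h)) for s, h in self.peaks))
        for size, height in self.peaks:
            if size <= 0 or height <= 0:
                raise MsapFormatError(
                    f"peak (size={size}, height={height}) for individual "
                    f"{self.individual_id!r}/{enzyme} must have positive size and height"
                )


@dataclass
class BandMatrixPair:
    """Paired binary band matrices, one per isoschizomer digest.

    ``hpa`` and ``msp`` are individuals x loci 0/1 integer arrays with
    identical shape and labelling: row i of both matrices is the same
    individual, column j the same locus.
    """

    loci: list[str]
    individuals: list[str]
    hpa: np.ndarray
    msp: np.ndarray

    def __post_init__(self) -> None:
        self.hpa = np.asarray(self.hpa, dtype=np.int8)
        self.msp = np.asarray(self.msp, dtype=np.int8)
        shape = (len(self.individuals), len(self.loci))
        if self.hpa.shape != shape or self.msp.shape != shape:
            raise MsapFormatError(
                f"band matrix shape mismatch: hpa {self.hpa.shape}, msp "
                f"{self.msp.shape}, expected {shape}"
            )
        for name, mat in (("hpa", self.hpa), ("msp", self.msp)):
            bad = ~np.isin(mat, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MsapFormatError(
                    f"non-binary entry in {name} matrix at individual "
                    f"{self.individuals[i]!r}, locus {self.loci[j]!r}"
                )
        if len(set(self.individuals)) != len(self.individuals):
            raise MsapFormatError("duplicated individual IDs in band matrix")
        if len(set(self.loci)) != len(self.loci):
            raise MsapFormatError("duplicated locus labels in band matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass
class SampleSheet:
    """Mapping from individual ID to population label (optional species tag)."""

    populations: dict[str, str]
    species: dict[str, str] = field(default_factory=dict)

    def population_of(self, individual: str) -> str:
        try:
            return self.populations[individual]
        except KeyError:
            raise MsapFormatError(f"individual {individual!r} missing from sample sheet") from None

    def groups(self, individuals: Sequence[str]) -> np.ndarray:
        """Population labels aligned with ``individuals``."""
        return np.array([self.population_of(i) for i in individuals], dtype=object)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.populations.values():
            seen.setdefault(pop, None)
        return list(seen)


@dataclass(frozen=True)
class BinningConfig:
    """Fragment-analysis scoring settings for peak binning.

    Defaults follow standard MS-AFLP scoring practice: analysis range
    50-500 bp, minimum peak height 50 RFU, maximum peak width 1.5 bp and a
    1.8 maximum peak-height ratio (higher peaks removed).
    """

    size_min: float = 50.0
    size_max: float = 500.0
    min_height: float = 50.0
    bin_width: float = 1.5
    max_height_ratio: float = 1.8

    def __post_init__(self) -> None:
        if not self.size_min < self.size_max:
            raise ValueError("size_min must be < size_max")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.min_height <= 0:
            raise ValueError("min_height must be positive")
        if self.max_height_ratio <= 1:
            raise ValueError("max_height_ratio must exceed 1")


# ---------------------------------------------------------------------------
# Band-matrix CSV dialect
# ---------------------------------------------------------------------------

_META_COLUMNS = 3  # population, individual, enzyme


def read_msap_table(path: str | Path) -> tuple[BandMatrixPair, SampleSheet]:
    """Read an msap-dialect band-matrix CSV.

    Layout: a header row whose first three cells name the metadata columns
    (population, individual, enzyme — any spelling) followed by locus
    labels; each data row carries the population label, individual ID,
    enzyme tag (``HPA``/``MSP``, case-insensitive) and one 0/1 cell per
    locus.  Every individual must contribute exactly one HPA and one MSP
    row.  A transposed or otherwise unrecognisable layout fails loudly.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise MsapFormatError(f"{path}: no data rows")
    header = [c.strip() for c in rows[0]]
    if len(header) <= _META_COLUMNS:
        raise MsapFormatError(f"{path}: header has no locus columns")
    loci = header[_META_COLUMNS:]

    enzyme_rows: dict[str, dict[str, list[int]]] = {e: {} for e in ENZYMES}
    populations: dict[str, str] = {}
    order: list[str] = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise MsapFormatError(f"{path}: row {r} has {len(row)} cells, expected {len(header)}")
        pop, ind, enz = (c.strip() for c in row[:_META_COLUMNS])
        enz = enz.upper()
        if enz not in ENZYMES:
            raise MsapFormatError(
                f"{path}: row {r}: enzyme tag {row[2]!r} is not HPA/MSP — "
                "unrecognised (possibly transposed) layout"
            )
        if ind in enzyme_rows[enz]:
            raise MsapFormatError(f"{path}: individual {ind!r} has duplicated {enz} rows")
        if ind in populations and populations[ind] != pop:
            raise MsapFormatError(f"{path}: individual {ind!r} listed under two populations")
        values = []
        for j, cell in enumerate(row[_META_COLUMNS:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise MsapFormatError(
                    f"{path}: non-binary cell {cell!r} at row {r}, column "
                    f"{loci[j]!r} (individual {ind!r})"
                )
            values.append(int(cell))
        enzyme_rows[enz][ind] = values
        populations.setdefault(ind, pop)
        if ind not in order:
            order.append(ind)

    missing = [
        (ind, enz)
        for ind in order
        for enz in ENZYMES
        if ind not in enzyme_rows[enz]
    ]
    if missing:
        ind, enz = missing[0]
        raise MsapFormatError(f"{path}: individual {ind!r} is missing its {enz} row")

    hpa = np.array([enzyme_rows["HPA"][i] for i in order], dtype=np.int8)
    msp = np.array([enzyme_rows["MSP"][i] for i in order], dtype=np.int8)
    pair = BandMatrixPair(loci=list(loci), individuals=order, hpa=hpa, msp=msp)
    sheet = SampleSheet(populations={i: populations[i] for i in order})
    return pair, sheet


def write_msap_table(pair: BandMatrixPair, sheet: SampleSheet, path: str | Path) -> Path:
    """Write a band-matrix pair back to the msap CSV dialect.

    Round-trips exactly through :func:`read_msap_table`: one HPA row then
    one MSP row per individual, locus columns in matrix order.
    """
    if pair.n_individuals == 0:
        raise MsapFormatError("refusing to write a band matrix with no individuals")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["population", "individual", "enzyme", *pair.loci])
        for i, ind in enumerate(pair.individuals):
            pop = sheet.population_of(ind)
            writer.writerow([pop, ind, "HPA", *pair.hpa[i].tolist()])
            writer.writerow([pop, ind, "MSP", *pair.msp[i].tolist()])
    return path


def read_peak_csv(path: str | Path) -> list[PeakTable]:
    """Read a GeneMapper-export-like peak CSV.

    Expected columns: ``individual``, ``enzyme``, ``size_bp``,
    ``height_rfu`` (header required, extra columns ignored).
    """
    df = pd.read_csv(path)
    required = {"individual", "enzyme", "size_bp", "height_rfu"}
    missing = required - set(df.columns)
    if missing:
        raise MsapFormatError(f"{path}: peak table missing columns {sorted(missing)}")
    tables = []
    for (ind, enz), sub in df.groupby(["individual", "enzyme"], sort=True):
        peaks = tuple(zip(sub["size_bp"].astype(float), sub["height_rfu"].astype(float)))
        tables.append(PeakTable(individual_id=str(ind), enzyme=str(enz), peaks=peaks))
    return tables


# ---------------------------------------------------------------------------
# Peak binning
# ---------------------------------------------------------------------------


def bin_peaks(tables: Iterable[PeakTable], config: BinningConfig | None = None) -> BandMatrixPair:
    """Bin fragment peaks into a binary band-matrix pair.

    Peaks outside ``[size_min, size_max]`` or below ``min_height`` are
    discarded.  Surviving peaks from all individuals and both enzymes are
    clustered on the size axis by greedy left-to-right 1-D clustering: a
    new locus starts whenever a peak lies more than ``bin_width`` bp above
    the first peak of the running locus.  Within each locus, peaks whose
    height exceeds ``max_height_ratio`` times the locus median height are
    removed before presence calling.  The result is order-invariant in
    both peaks and individuals (individuals are sorted lexicographically).
    """
    config = config or BinningConfig()
    tables = list(tables)
    individuals = sorted({t.individual_id for t in tables})
    by_key: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for t in tables:
        by_key.setdefault((t.individual_id, t.enzyme), []).extend(t.peaks)

    for ind in individuals:
        for enz in ENZYMES:
            if (ind, enz) not in by_key:
                raise MsapFormatError(f"individual {ind!r} has no {enz} peak table")

    # (size, height, individual, enzyme) survivors of the range/height filters
    survivors: list[tuple[float, float, str, str]] = []
    for (ind, enz), peaks in by_key.items():
        for size, height in peaks:
            if config.size_min <= size <= config.size_max and height >= config.min_height:
                survivors.append((size, height, ind, enz))
    if not survivors:
        raise EmptyAnalysisError("no peaks survive the analysis-range and height filters")

    survivors.sort(key=lambda p: (p[0], p[2], p[3], p[1]))

    clusters: list[list[tuple[float, float, str, str]]] = []
    for peak in survivors:
        if clusters and peak[0] - clusters[-1][0][0] <= config.bin_width:
            clusters[-1].append(peak)
        else:
            clusters.append([peak])

    ind_index = {ind: i for i, ind in enumerate(individuals)}
    hpa = np.zeros((len(individuals), len(clusters)), dtype=np.int8)
    msp = np.zeros((len(individuals), len(clusters)), dtype=np.int8)
    loci = []
    for j, cluster in enumerate(clusters):
        heights = np.array([h for _, h, _, _ in cluster])
        cutoff = config.max_height_ratio * float(np.median(heights))
        kept = [p for p in cluster if p[1] <= cutoff]
        center = float(np.mean([s for s, _, _, _ in kept]))
        loci.append(f"L{j + 1:03d}_{center:.1f}")
        for _, _, ind, enz in kept:
            mat = hpa if enz == "HPA" else msp
            mat[ind_index[ind], j] = 1  # binary collapse of multiple peaks
    return BandMatrixPair(loci=loci, individuals=individuals, hpa=hpa, msp=msp)
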