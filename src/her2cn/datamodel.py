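"""Domain types and file I/O for amplicon-based ERBB2 copy-number analysis.

The objects here mirror the artefacts of a clinical HER2 cross-platform
comparison: a targeted amplicon panel, per-sample read-count vectors,
per-case copy-number measurements from three platforms (FISH, MIP array,
amplicon sequencing), and the three-level HER2 classification they share.

A fully transcribed 29-case breast-cancer reference cohort (FISH copy
number, MIP/TuScan copy number, and the ERBB2/TP53 normalized-amplicon-
coverage ratio per case, with the published per-platform HER2 classes)
ships with the package and is loaded by :func:`load_reference_cohort`.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Her2Class",
    "Cohort",
    "Amplicon",
    "AmpliconPanel",
    "SampleCoverage",
    "CnMeasurement",
    "NacThreshold",
    "FishObservation",
    "CoverageFormatError",
    "DegenerateInputError",
    "default_panel",
    "read_panel",
    "write_panel",
    "read_coverage_matrix",
    "write_coverage_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_reference_cohort",
    "PUBLISHED_NAC_THRESHOLD",
]


class CoverageFormatError(ValueError):
    """A coverage matrix, panel or sample sheet violates its format contract."""


class DegenerateInputError(ValueError):
    """Input is syntactically valid but numerically degenerate (e.g. all-zero counts)."""


class Her2Class(enum.IntEnum):
    """Three-level HER2 status with the clinical ordering negative < equivocal < positive."""

    negative = 0
    equivocal = 1
    positive = 2

    def __str__(self) -> str:  # CSV/report rendering uses the bare name
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "Her2Class":
        try:
            return cls[label.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown HER2 class label: {label!r}") from None


class Cohort(str, enum.Enum):
    """Specimen role: tumor sample under test or copy-neutral calibration control."""

    tumor = "tumor"
    control = "control"


@dataclass(frozen=True)
class Amplicon:
    """One PCR amplicon of the targeted panel; coordinates are 1-based inclusive."""

    amplicon_id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"amplicon {self.amplicon_id!r} has an empty gene label")
        if self.start > self.end:
            raise ValueError(
                f"amplicon {self.amplicon_id!r}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class AmpliconPanel:
    """An ordered targeted panel with gene annotations.

    Parameters
    ----------
    amplicons
        Panel members in panel order.  Amplicon identifiers must be unique.

    Notes
    -----
    The dosage statistic downstream needs at least the ERBB2 and TP53
    amplicon groups; the default clinical panel carries 3 ERBB2 amplicons
    and 8 TP53 amplicons (see :func:`default_panel`).
    """

    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        ids = [a.amplicon_id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate amplicon ids in panel: {dupes}")

    @property
    def amplicon_ids(self) -> tuple[str, ...]:
        return tuple(a.amplicon_id for a in self.amplicons)

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct gene labels in panel order."""
        seen: dict[str, None] = {}
        for a in self.amplicons:
            seen.setdefault(a.gene, None)
        return tuple(seen)

    def amplicons_for(self, gene: str) -> tuple[Amplicon, ...]:
        hits = tuple(a for a in self.amplicons if a.gene == gene)
        if not hits:
            raise KeyError(f"gene {gene!r} not covered by this panel")
        return hits

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)


@dataclass
class SampleCoverage:
    """Raw read counts of one sequencing library over a panel.

    ``counts`` maps amplicon id to a non-negative integer read count.
    At least one amplicon must have coverage; an all-zero library is
    rejected because it cannot be normalized.
    """

    sample_id: str
    cohort: Cohort
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if isinstance(self.cohort, str):
            self.cohort = Cohort(self.cohort)
        for amp, c in self.counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
                raise CoverageFormatError(
                    f"sample {self.sample_id!r}, amplicon {amp!r}: "
                    f"count must be a non-negative integer, got {c!r}"
                )
        if self.counts and not any(self.counts.values()):
            raise DegenerateInputError(
                f"sample {self.sample_id!r} has zero coverage on every amplicon"
            )

    def validate_against(self, panel: AmpliconPanel) -> None:
        unknown = set(self.counts) - set(panel.amplicon_ids)
        if unknown:
            raise CoverageFormatError(
                f"sample {self.sample_id!r} has counts for amplicons absent "
                f"from the panel: {sorted(unknown)}"
            )


@dataclass
class CnMeasurement:
    """Per-case ERBB2 copy-number triple: FISH CN, MIP CN, and the NAC ratio.

    Optional per-platform HER2 classes carry the published calls; they can
    be re-derived from the numeric values with the classify operations.
    """

    case_id: str
    fish_cn: float | None = None
    mip_cn: float | None = None
    nac_ratio: float | None = None
    fish_class: Her2Class | None = None
    mip_class: Her2Class | None = None
    nac_class: Her2Class | None = None

    def __post_init__(self) -> None:
        import math

        for name in ("fish_cn", "mip_cn", "nac_ratio"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")


@dataclass(frozen=True)
class NacThreshold:
    """A calibrated NAC-ratio cutoff for calling an ERBB2 copy-number gain.

    A threshold calibrated from a control cohort is ``mean + 2*sd`` of the
    control ratios and carries its provenance (n, mean, sd).  A threshold
    adopted from the literature carries no provenance
    (see :data:`PUBLISHED_NAC_THRESHOLD`).
    """

    value: float
    control_n: int | None = None
    control_mean: float | None = None
    control_sd: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"threshold must be positive, got {self.value}")
        if self.control_n is not None:
            if self.control_n < 2:
                raise ValueError("threshold provenance requires >= 2 controls")
            expected = self.control_mean + 2.0 * self.control_sd
            if abs(self.value - expected) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError(
                    f"threshold {self.value} inconsistent with provenance "
                    f"mean+2sd = {expected}"
                )


#: Gain cutoff for the ERBB2/TP53 NAC ratio published for this assay,
#: calibrated by its authors as mean + 2*SD over 12 copy-neutral tonsil
#: controls.  The underlying control read counts are not public, so this
#: value cannot be re-derived here; it ships as a constant for classifying
#: the reference cohort.
PUBLISHED_NAC_THRESHOLD = NacThreshold(value=1.18)


@dataclass(frozen=True)
class FishObservation:
    """Two-observer FISH signal counts for one case.

    Each observer reports the total number of ERBB2 signals summed over
    ``cells_per_observer`` tumor-cell nuclei (50 in the clinical protocol);
    signal clusters enter as the observers' estimated per-cell totals.
    """

    case_id: str
    observer1_total: int
    observer2_total: int
    cells_per_observer: int = 50

    def __post_init__(self) -> None:
        if self.cells_per_observer <= 0:
            raise ValueError("cells_per_observer must be positive")
        for name in ("observer1_total", "observer2_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# Panel I/O and the default clinical panel
# ---------------------------------------------------------------------------

# Gene footprints (GRCh38, chr17) used to lay out plausible amplicon tiles.
_ERBB2_SPAN = (39_688_094, 39_728_660)
_TP53_SPAN = (7_668_421, 7_687_490)


def default_panel(n_background: int = 0) -> AmpliconPanel:
    """Build the default hotspot panel: 3 ERBB2 amplicons, 8 TP53 amplicons.

    Parameters
    ----------
    n_background
        Number of additional single-amplicon background genes (``BG1`` ...)
        appended after the two target genes, emulating the remainder of a
        multi-gene hotspot panel.  Background amplicons enter the per-sample
        normalization but not the ERBB2/TP53 ratio.
    """
    amps: list[Amplicon] = []
    e0, e1 = _ERBB2_SPAN
    step = (e1 - e0) // 3
    for i in range(3):
        amps.append(
            Amplicon(f"ERBB2_amp{i + 1}", "ERBB2", "chr17", e0 + i * step, e0 + i * step + 120)
        )
    t0, t1 = _TP53_SPAN
    step = (t1 - t0) // 8
    for i in range(8):
        amps.append(
            Amplicon(f"TP53_amp{i + 1}", "TP53", "chr17", t0 + i * step, t0 + i * step + 120)
        )
    for i in range(n_background):
        start = 1_000_000 + i * 10_000
        amps.append(Amplicon(f"BG{i + 1}_amp1", f"BG{i + 1}", "chr1", start, start + 120))
    return AmpliconPanel(tuple(amps))


def read_panel(path: str | Path) -> AmpliconPanel:
    """Read a panel definition from TSV (1-based inclusive) or BED.

    TSV columns: ``amplicon_id  gene  chrom  start  end``.  A ``.bed``
    extension switches to BED semantics (0-based half-open, gene in the
    name field, auto-generated amplicon ids ``<gene>_ampN``).
    """
    path = Path(path)
    amps: list[Amplicon] = []
    if path.suffix.lower() == ".bed":
        per_gene: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 4:
                    raise CoverageFormatError(f"{path}: BED line needs >= 4 fields: {line!r}")
                chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
                per_gene[gene] = per_gene.get(gene, 0) + 1
                amps.append(
                    Amplicon(f"{gene}_amp{per_gene[gene]}", gene, chrom, start + 1, end)
                )
    else:
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"amplicon_id", "gene", "chrom", "start", "end"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise CoverageFormatError(
                    f"{path}: panel TSV needs columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                amps.append(
                    Amplicon(
                        row["amplicon_id"],
                        row["gene"],
                        row["chrom"],
                        int(row["start"]),
                        int(row["end"]),
                    )
                )
    return AmpliconPanel(tuple(amps))


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["amplicon_id", "gene", "chrom", "start", "end"])
        for a in panel:
            w.writerow([a.amplicon_id, a.gene, a.chrom, a.start, a.end])


# ---------------------------------------------------------------------------
# Coverage-matrix I/O
# ---------------------------------------------------------------------------


def read_coverage_matrix(
    path: str | Path,
    cohorts: Mapping[str, Cohort | str] | None = None,
    control_ids: Iterable[str] | None = None,
) -> list[SampleCoverage]:
    """Read an amplicons-by-samples TSV of integer read counts.

    The header row lists sample ids; the first column is ``amplicon_id``.
    Every cell must be a non-negative integer — missing or non-integer
    cells are format errors naming the offending row/column.

    Samples default to the tumor cohort; pass ``cohorts`` (sample_id ->
    cohort) or ``control_ids`` to flag calibration controls.
    """
    path = Path(path)
    control_set = set(control_ids or ())
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CoverageFormatError(f"{path}: empty file") from None
        if not header or header[0] != "amplicon_id":
            raise CoverageFormatError(
                f"{path}: first header column must be 'amplicon_id', got {header[:1]}"
            )
        sample_ids = header[1:]
        if len(sample_ids) != len(set(sample_ids)):
            raise CoverageFormatError(f"{path}: duplicate sample ids in header")
        counts: dict[str, dict[str, int]] = {s: {} for s in sample_ids}
        seen_amps: set[str] = set()
        for row in reader:
            if not row:
                continue
            amp = row[0]
            if amp in seen_amps:
                raise CoverageFormatError(f"{path}: duplicate amplicon_id {amp!r}")
            seen_amps.add(amp)
            if len(row) != len(sample_ids) + 1:
                raise CoverageFormatError(
                    f"{path}: row {amp!r} has {len(row) - 1} cells, "
                    f"expected {len(sample_ids)}"
                )
            for sid, cell in zip(sample_ids, row[1:]):
                try:
                    value = int(cell)
                except ValueError:
                    raise CoverageFormatError(
                        f"{path}: non-integer count {cell!r} "
                        f"(amplicon {amp!r}, sample {sid!r})"
                    ) from None
                if value < 0:
                    raise CoverageFormatError(
                        f"{path}: negative count {value} (amplicon {amp!r}, sample {sid!r})"
                    )
                counts[sid][amp] = value
    samples = []
    for sid in sample_ids:
        if cohorts is not None and sid in cohorts:
            cohort = Cohort(cohorts[sid])
        elif sid in control_set:
            cohort = Cohort.control
        else:
            cohort = Cohort.tumor
        samples.append(SampleCoverage(sample_id=sid, cohort=cohort, counts=counts[sid]))
    return samples


def write_coverage_matrix(samples: Sequence[SampleCoverage], path: str | Path) -> None:
    """Write samples to the amplicons-by-samples TSV format (lossless round-trip)."""
    if not samples:
        raise ValueError("no samples to write")
    amp_ids = list(samples[0].counts)
    for s in samples[1:]:
        if set(s.counts) != set(amp_ids):
            raise CoverageFormatError(
                f"sample {s.sample_id!r} covers a different amplicon set"
            )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["amplicon_id"] + [s.sample_id for s in samples])
        for amp in amp_ids:
            w.writerow([amp] + [s.counts[amp] for s in samples])


# ---------------------------------------------------------------------------
# Sample sheets and the packaged reference cohort
# ---------------------------------------------------------------------------

_PLATFORM_COLUMNS = ("fish_cn", "mip_cn", "nac_ratio")
_CLASS_COLUMNS = ("fish_class", "mip_class", "nac_class")


def read_sample_sheet(path: str | Path) -> list[CnMeasurement]:
    """Read a per-case CSV with columns ``case_id`` plus any subset of
    ``fish_cn``, ``mip_cn``, ``nac_ratio`` (and optional ``*_class`` columns)."""
    path = Path(path)
    out: list[CnMeasurement] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "case_id" not in reader.fieldnames:
            raise CoverageFormatError(f"{path}: sample sheet needs a 'case_id' column")
        if not any(c in reader.fieldnames for c in _PLATFORM_COLUMNS):
            raise CoverageFormatError(
                f"{path}: sample sheet needs at least one of {_PLATFORM_COLUMNS}"
            )
        for row in reader:
            kwargs: dict = {"case_id": row["case_id"]}
            for col in _PLATFORM_COLUMNS:
                if row.get(col) not in (None, ""):
                    kwargs[col] = float(row[col])
            for col in _CLASS_COLUMNS:
                if row.get(col) not in (None, ""):
                    kwargs[col] = Her2Class.from_label(row[col])
            out.append(CnMeasurement(**kwargs))
    return out


def write_sample_sheet(cases: Sequence[CnMeasurement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", *_PLATFORM_COLUMNS, *_CLASS_COLUMNS])
        for c in cases:
            w.writerow(
                [
                    c.case_id,
                    *(getattr(c, col) if getattr(c, col) is not None else "" for col in _PLATFORM_COLUMNS),
                    *(str(getattr(c, col)) if getattr(c, col) is not None else "" for col in _CLASS_COLUMNS),
                ]
            )


def load_reference_cohort() -> list[CnMeasurement]:
    """Load the packaged 29-case breast-cancer reference cohort.

    Per case: FISH average ERBB2 CN, MIP/TuScan CN, ERBB2/TP53 NAC ratio,
    and the published per-platform HER2 classes.  The source table prints
    decimal commas; the packaged transcription uses decimal points.
    """
    ref = resources.files("her2cn.data").joinpath("reference_cohort.csv")
    out: list[CnMeasurement] = []
    with ref.open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CnMeasurement(
                    case_id=row["case_id"],
                    fish_cn=float(row["fish_cn"]),
                    mip_cn=float(row["mip_cn"]),
                    nac_ratio=float(row["nac_ratio"]),
                    fish_class=Her2Class.from_label(row["fish_class"]),
                    mip_class=Her2Class.from_label(row["mip_class"]),
                    nac_class=Her2Class.from_label(row["nac_class"]),
                )
            )
    if len(out) != 29:
        raise RuntimeError(f"reference cohort corrupt: expected 29 cases, got {len(out)}")
    return out
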