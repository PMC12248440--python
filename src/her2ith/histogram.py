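"""Per-nucleus FISH signal counts, copy-number histograms, and tumor summaries.

A dual-probe FISH assay counts two fluorescent signals in each tumor nucleus:
HER2 (the gene probe) and CEP17 (the chromosome-17 centromere reference,
~2 copies in a diploid cell).  The per-tumor HER2 copy-number *histogram* —
how many nuclei carried 0, 1, 2, ... HER2 signals — is the object the
downstream mixture analysis operates on.

Conventions
-----------
* Histogram bins are raw integer signal counts; no overflow/clipping bin.
* The FISH ratio is total HER2 signals over total CEP17 signals across all
  counted nuclei (equivalently the ratio of means), the dual-probe kit
  convention.
* A tumor is called HER2-positive when the mean HER2 copy number per cell
  strictly exceeds 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CellCounts",
    "SignalHistogram",
    "TumorSummary",
    "HistogramFormatError",
    "histogram_from_cells",
    "read_histogram_tsv",
    "write_histogram_tsv",
    "read_cells_tsv",
    "write_cells_tsv",
    "summarize_tumor",
]


class HistogramFormatError(ValueError):
    """Raised for malformed histogram TSV files; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class CellCounts:
    """Paired HER2 and CEP17 signal counts for the nuclei of one tumor.

    Parameters
    ----------
    her2, cep17 : array-like of int
        Signals per nucleus, same length, all entries >= 0, length >= 1.
    """

    her2: np.ndarray
    cep17: np.ndarray

    def __post_init__(self):
        her2 = np.asarray(self.her2, dtype=np.int64)
        cep17 = np.asarray(self.cep17, dtype=np.int64)
        if her2.ndim != 1 or cep17.ndim != 1:
            raise ValueError("signal counts must be 1-D sequences")
        if her2.size == 0:
            raise ValueError("at least one nucleus is required")
        if her2.size != cep17.size:
            raise ValueError(
                f"her2 ({her2.size}) and cep17 ({cep17.size}) lengths differ"
            )
        if (her2 < 0).any() or (cep17 < 0).any():
            raise ValueError("signal counts must be non-negative")
        object.__setattr__(self, "her2", her2)
        object.__setattr__(self, "cep17", cep17)

    @property
    def n_cells(self) -> int:
        return int(self.her2.size)


@dataclass(frozen=True)
class SignalHistogram:
    """Binned HER2 copy-number distribution of one tumor.

    ``bins`` maps integer HER2 copy number -> nucleus count.  Mass is
    conserved: the bin counts sum to ``n_cells``.
    """

    bins: dict[int, int]

    def __post_init__(self):
        clean: dict[int, int] = {}
        for k, v in self.bins.items():
            ik, iv = int(k), int(v)
            if ik != k or iv != v:
                raise ValueError(f"non-integer histogram entry {k!r}: {v!r}")
            if ik < 0:
                raise ValueError(f"negative copy-number bin {ik}")
            if iv < 0:
                raise ValueError(f"negative cell count in bin {ik}")
            if iv > 0:
                clean[ik] = iv
        if not clean:
            raise ValueError("histogram has no cells")
        object.__setattr__(self, "bins", dict(sorted(clean.items())))

    @property
    def n_cells(self) -> int:
        return sum(self.bins.values())

    def values_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Occupied bin centers and their multiplicities as float arrays."""
        xs = np.array(sorted(self.bins), dtype=float)
        ws = np.array([self.bins[int(x)] for x in xs], dtype=float)
        return xs, ws

    @property
    def mean(self) -> float:
        xs, ws = self.values_weights()
        return float(np.average(xs, weights=ws))

    @property
    def var(self) -> float:
        xs, ws = self.values_weights()
        m = np.average(xs, weights=ws)
        return float(np.average((xs - m) ** 2, weights=ws))


@dataclass(frozen=True)
class TumorSummary:
    """First-line FISH summary of one tumor."""

    mean_her2: float
    fish_ratio: float
    her2_positive: bool = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "her2_positive", self.mean_her2 > 2.0)


def histogram_from_cells(cells: CellCounts) -> SignalHistogram:
    """Bin the HER2 signal counts of a tumor into a copy-number histogram."""
    values, counts = np.unique(cells.her2, return_counts=True)
    return SignalHistogram({int(v): int(c) for v, c in zip(values, counts)})


def summarize_tumor(cells: CellCounts) -> TumorSummary:
    """Mean HER2 copies, HER2/CEP17 FISH ratio, and the positivity call.

    Raises
    ------
    ValueError
        If every nucleus has zero CEP17 signals (the ratio is undefined).
    """
    total_cep17 = int(cells.cep17.sum())
    if total_cep17 == 0:
        raise ValueError("FISH ratio undefined: total CEP17 signal count is zero")
    mean_her2 = float(cells.her2.mean())
    ratio = float(cells.her2.sum()) / total_cep17
    return TumorSummary(mean_her2=mean_her2, fish_ratio=ratio)


_TSV_HEADER = "copy_number\tcell_count"


def write_histogram_tsv(hist: SignalHistogram, path: str | Path) -> None:
    """Write a histogram as a two-column TSV (header ``copy_number\\tcell_count``)."""
    lines = [_TSV_HEADER]
    lines += [f"{k}\t{v}" for k, v in hist.bins.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_histogram_tsv(path: str | Path) -> SignalHistogram:
    """Read a two-column histogram TSV; strict inverse of :func:`write_histogram_tsv`."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise HistogramFormatError("empty file")
    header = lines[0].strip()
    if header.split("\t") != _TSV_HEADER.split("\t"):
        raise HistogramFormatError(
            f"expected header {_TSV_HEADER!r}, got {header!r}", line=1
        )
    bins: dict[int, int] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise HistogramFormatError(
                f"expected two tab-separated fields, got {len(parts)}", line=lineno
            )
        try:
            k, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise HistogramFormatError(str(exc), line=lineno) from exc
        if k < 0:
            raise HistogramFormatError(f"negative copy-number bin {k}", line=lineno)
        if v < 0:
            raise HistogramFormatError(f"negative cell count {v}", line=lineno)
        if k in bins:
            raise HistogramFormatError(f"duplicate bin {k}", line=lineno)
        bins[k] = v
    if not bins or all(v == 0 for v in bins.values()):
        raise HistogramFormatError("no cells in data section")
    return SignalHistogram(bins)


_CELLS_HEADER = "nucleus_id\ther2_signals\tcep17_signals"


def write_cells_tsv(cells: CellCounts, path: str | Path) -> None:
    """Write a per-nucleus signal-count table (three tab-separated columns)."""
    lines = [_CELLS_HEADER]
    lines += [
        f"{i}\t{h}\t{c}" for i, (h, c) in enumerate(zip(cells.her2, cells.cep17), 1)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cells_tsv(path: str | Path) -> CellCounts:
    """Read a per-nucleus signal-count table written by :func:`write_cells_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip().split("\t") != _CELLS_HEADER.split("\t"):
        raise HistogramFormatError(f"expected header {_CELLS_HEADER!r}", line=1)
    her2, cep17 = [], []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 3:
            raise HistogramFormatError("expected three fields", line=lineno)
        try:
            her2.append(int(parts[1]))
            cep17.append(int(parts[2]))
        except ValueError as exc:
            raise HistogramFormatError(str(exc), line=lineno) from exc
    if not her2:
        raise HistogramFormatError("no nuclei in data section")
    return CellCounts(her2=np.array(her2), cep17=np.array(cep17))
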