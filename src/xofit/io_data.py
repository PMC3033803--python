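"""Data containers and file I/O for crossover observations.

Two experimental observables are supported:

* continuous crossover positions per bivalent cell (e.g. immunostained foci
  or late recombination nodules on synaptonemal complexes), in any physical
  or genetic unit;
* marker segregation data at the gamete level (backcross / doubled-haploid
  genotype matrices), optionally with a genetic map.

All model fitting happens in genetic space, on the Morgan scale of the
gamete, where the bivalent carries exactly 2 crossovers per Morgan.
Positions are 0-based and intervals half-open ``[a, b)``.

File formats (all plain text, metadata lines prefixed with ``#``):

* CO positions: line 1 ``#length <float> <unit>``, then one
  whitespace-separated row of positions per cell (empty row = 0-CO cell).
* Genotypes: TSV with a header row of marker names, first column the
  individual id, alleles coded ``A``/``B``/``-`` by default.
* Genetic map: TSV of ``marker<TAB>position_cM`` with strictly increasing
  positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults

__all__ = [
    "ChromosomeFrame",
    "BivalentDataset",
    "GeneticMap",
    "GameteDataset",
    "read_bivalent_positions",
    "write_bivalent_positions",
    "read_genetic_map",
    "write_genetic_map",
    "read_segregation",
    "write_segregation",
    "to_genetic_space",
    "estimate_interval_lengths",
]

_UNITS = ("um", "Mb", "cM", "morgan")


@dataclass(frozen=True)
class ChromosomeFrame:
    """Coordinate system of one chromosome.

    ``length`` is expressed in ``source_units``; once data are converted to
    genetic space the unit is ``morgan`` and ``length_morgans`` is defined.
    The bivalent crossover intensity is a fixed convention (2 per Morgan,
    i.e. 1 per Morgan per gamete) and deliberately not settable.
    """

    length: float
    source_units: str = "morgan"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.source_units not in _UNITS:
            raise ValueError(
                f"unknown unit {self.source_units!r}; expected one of {_UNITS}"
            )

    @property
    def bivalent_intensity(self) -> float:
        return defaults.BIVALENT_INTENSITY

    @property
    def length_morgans(self) -> float:
        if self.source_units == "morgan":
            return self.length
        if self.source_units == "cM":
            return self.length / 100.0
        raise ValueError(
            f"length is in {self.source_units!r}; convert with "
            "to_genetic_space first"
        )


class BivalentDataset:
    """Per-cell sorted crossover positions plus their coordinate frame."""

    def __init__(self, cells, frame: ChromosomeFrame):
        self.frame = frame
        clean = []
        for i, cell in enumerate(cells):
            arr = np.sort(np.asarray(cell, dtype=float))
            if arr.size and (arr[0] < 0.0 or arr[-1] > frame.length):
                raise ValueError(
                    f"cell {i}: position outside [0, {frame.length}]"
                )
            clean.append(arr)
        self.cells: list[np.ndarray] = clean
        self._counts: np.ndarray | None = None

    @classmethod
    def from_sorted(cls, cells, frame: ChromosomeFrame) -> "BivalentDataset":
        """Trusted constructor for internally generated, already-sorted cells."""
        obj = cls.__new__(cls)
        obj.frame = frame
        obj.cells = list(cells)
        obj._counts = None
        return obj

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def counts(self) -> np.ndarray:
        if self._counts is None:
            self._counts = np.array([c.size for c in self.cells], dtype=int)
        return self._counts

    def pooled_positions(self) -> np.ndarray:
        if not self.cells:
            return np.empty(0)
        return np.concatenate(self.cells) if self.cells else np.empty(0)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BivalentDataset)
            and self.frame == other.frame
            and len(self.cells) == len(other.cells)
            and all(np.array_equal(a, b) for a, b in zip(self.cells, other.cells))
        )


@dataclass(frozen=True)
class GeneticMap:
    """Marker names and positions in Morgans (nondecreasing).

    Zero-length intervals may arise from recombination-fraction estimation
    (no observed recombinant); they are flagged and excluded from
    likelihood computations.  Maps read from files must be strictly
    increasing.
    """

    names: tuple[str, ...]
    positions_morgans: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_morgans, dtype=float)
        object.__setattr__(self, "positions_morgans", pos)
        if len(self.names) != pos.size:
            raise ValueError("names and positions must align")
        if pos.size < 2:
            raise ValueError("a map needs at least two markers")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate marker names")
        if np.any(np.diff(pos) < 0):
            raise ValueError("marker positions must be nondecreasing")

    @property
    def interval_lengths(self) -> np.ndarray:
        return np.diff(self.positions_morgans)

    @property
    def span(self) -> float:
        return float(self.positions_morgans[-1] - self.positions_morgans[0])

    @property
    def n_markers(self) -> int:
        return len(self.names)


class GameteDataset:
    """Genotype matrix (individuals x markers) with optional genetic map.

    Alleles are the two parental classes of a backcross or doubled-haploid
    design; missing calls are ``NaN``.  The recombination pattern of each
    gamete is the parity vector over its merged marker partition: intervals
    run between consecutive *non-missing* calls, and parity 1 marks a
    detectable (odd) number of transmitted crossovers.
    """

    def __init__(self, genotypes: pd.DataFrame, gmap: GeneticMap | None = None):
        if genotypes.shape[1] < 2:
            raise ValueError("need at least two markers")
        if gmap is not None and list(genotypes.columns) != list(gmap.names):
            raise ValueError("marker names of genotypes and map disagree")
        bad = set(genotypes.stack().unique()) - {"A", "B"}
        if bad:
            raise ValueError(
                f"non-biallelic allele codes {sorted(bad)}; only the two "
                "parental classes (and missing) are supported"
            )
        self.genotypes = genotypes
        self.map = gmap
        self._partitions: list | None = None

    @property
    def n_gametes(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def require_map(self) -> GeneticMap:
        if self.map is None:
            raise ValueError(
                "no genetic map attached; supply one or call "
                "estimate_interval_lengths"
            )
        return self.map

    def with_map(self, gmap: GeneticMap) -> "GameteDataset":
        return GameteDataset(self.genotypes, gmap)

    def partitions(self) -> list[list[tuple[int, int, int]]]:
        """Per-gamete merged-interval tokens ``(marker_i, marker_j, parity)``.

        Intervals join consecutive non-missing markers (merging across
        missing calls); a gamete with fewer than two informative markers
        yields an empty token list.  Flipping every allele of a gamete
        leaves its tokens unchanged.  Computed once and cached.
        """
        if self._partitions is None:
            vals = self.genotypes.to_numpy(dtype=object)
            out = []
            for row in vals:
                informative = [
                    i for i, v in enumerate(row) if isinstance(v, str)
                ]
                tokens = []
                for a, b in zip(informative, informative[1:]):
                    tokens.append((a, b, int(row[a] != row[b])))
                out.append(tokens)
            self._partitions = out
        return self._partitions

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GameteDataset)
            and self.genotypes.equals(other.genotypes)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bivalent_positions(path) -> BivalentDataset:
    """Read a crossover-position file (one cell per row).

    The header line declares the chromosome length and units; positions are
    returned in those source units, sorted within each cell.  A position
    exactly at the declared length is accepted and clamped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#length"):
        raise ValueError(f"{path}: missing '#length <float> <unit>' header")
    parts = lines[0].split()
    if len(parts) != 3:
        raise ValueError(f"{path}:1: malformed length header")
    try:
        length = float(parts[1])
    except ValueError as exc:
        raise ValueError(f"{path}:1: unparseable length {parts[1]!r}") from exc
    unit = parts[2]
    cells = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line.startswith("#"):
            continue
        tokens = line.split()
        try:
            vals = np.array([float(t) for t in tokens])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable token") from exc
        if vals.size and vals.min() < 0:
            raise ValueError(f"{path}:{lineno}: negative position")
        if vals.size and vals.max() > length:
            raise ValueError(
                f"{path}:{lineno}: position {vals.max()} exceeds declared "
                f"length {length}"
            )
        cells.append(np.sort(vals))
    return BivalentDataset(cells, ChromosomeFrame(length, unit))


def write_bivalent_positions(data: BivalentDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#length {data.frame.length:.17g} {data.frame.source_units}\n")
        for cell in data.cells:
            fh.write(" ".join(f"{x:.17g}" for x in cell) + "\n")


def read_genetic_map(path) -> GeneticMap:
    """Read a TSV of marker / position-cM pairs (strictly increasing)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["marker", "position_cM"])
    pos = df["position_cM"].to_numpy(dtype=float) / 100.0
    if np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: map positions must be strictly increasing")
    return GeneticMap(tuple(df["marker"].astype(str)), pos)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#marker\tposition_cM\n")
        for name, pos in zip(gmap.names, gmap.positions_morgans):
            fh.write(f"{name}\t{100.0 * pos:.17g}\n")


def read_segregation(
    genotype_path,
    map_path=None,
    codes: tuple[str, str, str] = ("A", "B", "-"),
) -> GameteDataset:
    """Read a gamete genotype matrix and (optionally) its genetic map.

    ``codes`` gives the two parental allele codes and the missing code.
    Heterozygote or other codes are rejected: the design must be a
    backcross or doubled-haploid panel, where each individual reveals a
    single gamete.
    """
    code_a, code_b, code_missing = codes
    with open(genotype_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"{genotype_path}: duplicate marker names")
    df = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
    recode = {code_a: "A", code_b: "B", code_missing: np.nan}
    arr = df.to_numpy(dtype=object)
    bad = {v for v in arr.ravel() if isinstance(v, str)} - set(recode)
    if bad:
        raise ValueError(
            f"{genotype_path}: unsupported allele codes {sorted(bad)} "
            f"(expected {codes}; heterozygotes are not supported)"
        )
    out = np.full(arr.shape, np.nan, dtype=object)
    for code, val in recode.items():
        out[arr == code] = val
    geno = pd.DataFrame(out, index=df.index, columns=df.columns)
    gmap = None
    if map_path is not None:
        gmap = read_genetic_map(map_path)
        if len(gmap.names) != geno.shape[1]:
            raise ValueError(
                f"marker count mismatch: {geno.shape[1]} genotype columns "
                f"vs {len(gmap.names)} map entries"
            )
        if list(geno.columns) != list(gmap.names):
            raise ValueError("marker names of genotypes and map disagree")
    return GameteDataset(geno, gmap)


def write_segregation(data: GameteDataset, genotype_path, map_path=None) -> None:
    out = data.genotypes.fillna("-")
    out.to_csv(genotype_path, sep="\t", index_label="id")
    if map_path is not None:
        write_genetic_map(data.require_map(), map_path)


# ---------------------------------------------------------------------------
# Genetic-space conversion
# ---------------------------------------------------------------------------


def to_genetic_space(
    data: BivalentDataset, n_bins: int = defaults.CDF_BINS
) -> BivalentDataset:
    """Map physical crossover positions onto the Morgan scale.

    The genetic length is fixed by the bivalent convention,
    ``L = (mean CO count per cell) / 2`` Morgans, and each position ``x`` is
    mapped to ``L * C(x)`` where ``C`` is the pooled empirical CDF of all
    crossover positions, binned into ``n_bins`` equal physical bins with
    linear interpolation inside bins.  By construction the pooled crossover
    density is uniform on ``[0, L]`` in the output.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    pooled = data.pooled_positions()
    if pooled.size == 0:
        raise ValueError(
            "dataset has no crossovers: genetic length is undefined"
        )
    L = float(np.mean(data.counts()) / defaults.BIVALENT_INTENSITY)
    phys_len = data.frame.length
    edges = np.linspace(0.0, phys_len, n_bins + 1)
    hist, _ = np.histogram(np.clip(pooled, 0.0, phys_len), bins=edges)
    cdf_at_edges = np.concatenate([[0.0], np.cumsum(hist) / pooled.size])
    cells = [
        L * np.interp(np.clip(c, 0.0, phys_len), edges, cdf_at_edges)
        for c in data.cells
    ]
    return BivalentDataset(cells, ChromosomeFrame(L, "morgan"))


def estimate_interval_lengths(data: GameteDataset) -> GeneticMap:
    """Estimate marker interval lengths from recombination fractions.

    Map-function-free: the genetic length of interval j is taken to be the
    observed recombination fraction between its flanking markers, using
    gametes where both calls are present.  Fractions at or above 0.5 are
    capped at 0.4999 with a warning; an interval without informative
    gametes is an error.
    """
    vals = data.genotypes.to_numpy(dtype=object)
    n_int = data.n_markers - 1
    lengths = np.empty(n_int)
    for j in range(n_int):
        a = vals[:, j]
        b = vals[:, j + 1]
        ok = np.array(
            [isinstance(x, str) and isinstance(y, str) for x, y in zip(a, b)]
        )
        n_inf = int(ok.sum())
        if n_inf == 0:
            raise ValueError(
                f"interval {j} ({data.genotypes.columns[j]} - "
                f"{data.genotypes.columns[j + 1]}) has no informative gametes"
            )
        rec = float(np.sum(a[ok] != b[ok]) / n_inf)
        if rec >= 0.5:
            warnings.warn(
                f"interval {j}: recombination fraction {rec:.3f} >= 0.5, "
                "capped at 0.4999 (markers effectively unlinked)",
                stacklevel=2,
            )
            rec = 0.4999
        lengths[j] = rec
    positions = np.concatenate([[0.0], np.cumsum(lengths)])
    return GeneticMap(tuple(str(c) for c in data.genotypes.columns), positions)
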