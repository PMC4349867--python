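"""Genome model and heterozygous marker map.

The coordinate frame for the whole pipeline: a diploid hybrid genome with 16
chromosomes and an ordered map of heterozygous SNP markers. Positions are
1-based inclusive base pairs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: S. cerevisiae chromosome lengths (bp, R64 scale), the default genome for
#: the simulator (~12.07 Mb total).
YEAST_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}


@dataclass(frozen=True)
class GenomeModel:
    """Named chromosomes with lengths in bp.

    Parameters
    ----------
    lengths
        Mapping of chromosome name to length in bp; insertion order defines
        chromosome order. All lengths must be positive.
    """

    lengths: dict[str, int] = field(
        default_factory=lambda: dict(YEAST_CHROM_LENGTHS)
    )

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome must have at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __len__(self) -> int:
        return len(self.lengths)


class MarkerMap:
    """Ordered heterozygous SNP positions on a genome.

    Wraps a DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``id``,
    sorted by chromosome (genome order) then position, unique positions per
    chromosome.
    """

    COLUMNS = ("chrom", "pos", "id")

    def __init__(self, df: pd.DataFrame, genome: GenomeModel):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        order = {name: i for i, name in enumerate(genome.names)}
        unknown = set(df["chrom"]) - set(order)
        if unknown:
            raise ValueError(f"markers on unknown chromosomes: {sorted(unknown)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if sub["pos"].duplicated().any():
                raise ValueError(f"duplicate marker positions on {chrom}")
            if (sub["pos"] < 1).any() or (sub["pos"] > genome.lengths[chrom]).any():
                raise ValueError(f"marker position outside {chrom} bounds")
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index slice of the markers on one chromosome."""
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions[self.chrom_slice(chrom)]

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genome: GenomeModel | None = None) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        if genome is None:
            # infer lengths from the data (markers bound each chromosome)
            lengths = {
                str(c): int(sub["pos"].max())
                for c, sub in df.groupby("chrom", sort=False)
            }
            genome = GenomeModel(lengths)
        return cls(df, genome)
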