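"""Genotype matrix container and tab-delimited IO.

Calls are encoded as small integers: ``A`` (0) for the first parent's
allele, ``B`` (1) for the second parent's, ``HET`` (2) for residual
heterozygotes and ``MISSING`` (-1) for failed or masked calls.  By
convention A is the reference-assembly parent (the elite line) and B the
resequenced wild parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A: int = 0
B: int = 1
HET: int = 2
MISSING: int = -1

#: symbol used in text files for each code
SYMBOLS = {A: "A", B: "B", HET: "H", MISSING: "-"}
CODES = {v: k for k, v in SYMBOLS.items()}


@dataclass
class GenotypeMatrix:
    """Markers x individuals call matrix with marker coordinates.

    Parameters
    ----------
    markers : pandas.DataFrame
        Indexed by marker id, with at least ``scaffold`` and ``bp``
        columns (0-based position of the marker on its scaffold).
    individuals : list of str
        RIL identifiers, one per matrix column.
    calls : numpy.ndarray of int8, shape (n_markers, n_individuals)
        Encoded calls.
    """

    markers: pd.DataFrame
    individuals: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame of A/B/H/- symbols with coordinate columns."""
        sym = pd.DataFrame(
            np.vectorize(SYMBOLS.get)(self.calls),
            index=self.markers.index,
            columns=self.individuals,
        )
        return pd.concat([self.markers, sym], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="marker")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="marker")
        coord_cols = [c for c in df.columns if c in ("chrom", "scaffold", "bp")]
        individuals = [c for c in df.columns if c not in coord_cols]
        sym = df[individuals].to_numpy(dtype=object)
        calls = np.vectorize(CODES.get)(sym).astype(np.int8)
        return cls(markers=df[coord_cols], individuals=individuals, calls=calls)

    def subset(self, marker_ids) -> "GenotypeMatrix":
        idx = self.markers.index.get_indexer(marker_ids)
        if (idx < 0).any():
            raise KeyError("unknown marker id in subset request")
        return GenotypeMatrix(
            markers=self.markers.iloc[idx].copy(),
            individuals=list(self.individuals),
            calls=self.calls[idx],
        )
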