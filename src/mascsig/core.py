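"""Shared containers and validation helpers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneSignature:
    """An ordered set of gene identifiers, all treated as up-genes.

    Parameters
    ----------
    genes : list of str
        Unique gene identifiers, order preserved.
    directions : dict, optional
        Per-gene direction; +1 throughout this package (up-regulated
        signatures). Kept explicit so mixed signatures can be represented.
    provenance : str
        Free-text note on how the signature was derived.
    """

    genes: list[str]
    directions: dict[str, int] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("GeneSignature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers in signature: {dupes}")
        if not self.directions:
            self.directions = {g: 1 for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions


def check_matrix(matrix) -> None:
    """Validate an expression matrix (genes x samples DataFrame).

    Raises ``ValueError`` on duplicate gene/sample identifiers or
    non-finite values.
    """
    import numpy as np

    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
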