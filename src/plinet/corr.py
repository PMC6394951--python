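"""Network strength vs. behavior: Pearson correlation with maxT FWE.

For each behavioral variable family, the per-subject network strength (the
mean PLI over the significant network's edges) is correlated with every
variable in the family.  Family-wise error is controlled by permutation:
the strength vector is shuffled against all variables jointly, the
maximal absolute correlation across the family is recorded per
permutation, and each pair's ``p_fwe`` is the proportion of those maxima
at least as large as the observed |r|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seeding import derive_rng
from .connectivity import ConnMatrix
from .netstats import Edge

__all__ = ["CorrFamily", "network_strength", "perm_corr_fwe"]


@dataclass
class CorrFamily:
    """One FWE family: a strength vector and named behavioral variables."""

    strengths: np.ndarray
    variables: Mapping[str, np.ndarray]
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.variables = {k: np.asarray(v, dtype=float)
                          for k, v in self.variables.items()}
        n = self.strengths.size
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if not self.variables:
            raise ValueError("family must contain at least one variable")
        for k, v in self.variables.items():
            if v.size != n:
                raise ValueError(f"variable {k!r} has {v.size} values for "
                                 f"{n} subjects")
        if self.n_perm < 1:
            raise ValueError("need at least one permutation")


def network_strength(matrix: ConnMatrix | np.ndarray,
                     edges: Sequence[Edge | tuple[int, int]]) -> float:
    """Mean connection strength over a network's edges."""
    values = matrix.values if isinstance(matrix, ConnMatrix) else np.asarray(matrix)
    if len(edges) == 0:
        raise ValueError("network strength of an empty network is undefined")
    idx = [(e.i, e.j) if isinstance(e, Edge) else (int(e[0]), int(e[1]))
           for e in edges]
    for i, j in idx:
        if not (0 <= i < values.shape[0] and 0 <= j < values.shape[1]):
            raise ValueError(f"edge ({i}, {j}) outside the matrix")
    return float(np.mean([values[i, j] for i, j in idx]))


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    return (x - x.mean()) / (s * np.sqrt(x.size))


def perm_corr_fwe(family: CorrFamily, add_one: bool = False
                  ) -> dict[str, tuple[float, float]]:
    """Observed Pearson r and maxT-permutation ``p_fwe`` per variable.

    One joint shuffle of the strength vector per permutation preserves the
    correlation structure among the behavioral variables.  With
    ``add_one`` the (obs+1)/(perm+1) convention is used instead of the
    plain proportion.
    """
    z = _standardize(family.strengths)
    names = list(family.variables)
    B = np.column_stack([_standardize(family.variables[k]) for k in names])
    obs_r = z @ B                                       # (K,)

    rng = derive_rng(family.seed, "perm-corr")
    n = z.size
    perm_z = np.empty((family.n_perm, n))
    for p in range(family.n_perm):
        perm_z[p] = z[rng.permutation(n)]
    max_abs = np.abs(perm_z @ B).max(axis=1)            # (P,)

    out: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(names):
        ge = int((max_abs >= abs(obs_r[k])).sum())
        if add_one:
            p_fwe = (ge + 1) / (family.n_perm + 1)
        else:
            p_fwe = ge / family.n_perm
        out[name] = (float(obs_r[k]), float(p_fwe))
    return out
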