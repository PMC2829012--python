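"""Geometric model of tag formation under incomplete restriction digestion.

In SAGE/DGE library construction an anchoring enzyme (AE) cleaves cDNA at
specific motif sites. Only the 3'-most site that is *actually* cleaved yields
an observable tag, because only the bead-bound 3' fragment is retained. With
a per-site cleavage probability ``p`` acting independently across sites, the
probability that the tag forms at site ``j`` (counting 1, 2, ... from the 3'
end) is geometric, ``(1-p)**(j-1) * p``: sites 1..j-1 escape cleavage and
site ``j`` is cut.

A gene's *tag formation probability* ``phi`` is the sum of these geometric
terms over its unambiguous sites (ambiguous sites produce tags that cannot be
assigned to a single gene and are discarded upstream). For a gene whose
``k`` sites are all unambiguous this telescopes to ``1 - (1-p)**k``. Genes
with no unambiguous site are unobservable and must be excluded before any
downstream inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CleavageModel",
    "GeneSiteStructure",
    "UnobservableGeneError",
    "site_tag_prob",
    "tag_formation_prob",
    "phi_from_site_counts",
    "simulate_site_structures",
    "write_site_structures",
    "read_site_structures",
]


class UnobservableGeneError(ValueError):
    """Raised for a gene with no unambiguous AE site (phi would be 0)."""


@dataclass(frozen=True)
class CleavageModel:
    """Anchoring-enzyme cleavage efficiency.

    Parameters
    ----------
    p : float
        Probability that the AE cleaves any given site, in (0, 1]. Assumed
        constant across sites and genes within a library, and known (it is
        estimated from the tag-position distribution upstream of this tool).
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"cleavage probability must be in (0, 1], got {self.p}")


@dataclass(frozen=True)
class GeneSiteStructure:
    """AE-site layout of a single gene.

    Sites are indexed 1..k starting from the 3'-most site (index 1 is the
    site closest to the bead); ``unambiguous[j-1]`` flags whether site ``j``
    yields a uniquely mappable tag.
    """

    gene_id: str
    k: int
    unambiguous: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"site count must be >= 0, got {self.k}")
        flags = tuple(bool(f) for f in self.unambiguous) or (True,) * self.k
        if len(flags) != self.k:
            raise ValueError(
                f"gene {self.gene_id}: {len(flags)} ambiguity flags for k={self.k} sites"
            )
        object.__setattr__(self, "unambiguous", flags)


def site_tag_prob(j: int, model: CleavageModel) -> float:
    """Probability that the observable tag forms at site ``j``.

    ``j`` counts 1-based from the 3' end; the value is the geometric mass
    ``(1-p)**(j-1) * p``.
    """
    if not isinstance(j, (int, np.integer)) or isinstance(j, bool):
        raise TypeError(f"site index must be an integer, got {j!r}")
    if j < 1:
        raise ValueError(f"site index must be >= 1, got {j}")
    p = model.p
    return (1.0 - p) ** (j - 1) * p


def tag_formation_prob(structure: GeneSiteStructure, model: CleavageModel) -> float:
    """Tag formation probability phi of a gene: geometric mass summed over
    its unambiguous sites.

    Raises
    ------
    UnobservableGeneError
        If the gene has no unambiguous site; such genes can never contribute
        a usable tag and must be excluded from the library.
    """
    js = np.flatnonzero(structure.unambiguous) + 1
    if js.size == 0:
        raise UnobservableGeneError(
            f"gene {structure.gene_id!r} has no unambiguous AE site; "
            "it is unobservable and must be excluded"
        )
    p = model.p
    # (1-p)**0 == 1 even at p == 1, so the geometric sum covers perfect digestion
    return float(np.sum((1.0 - p) ** (js - 1.0) * p))


def phi_from_site_counts(k: np.ndarray | Sequence[int], p: float) -> np.ndarray:
    """Vectorized phi for genes whose sites are all unambiguous:
    ``1 - (1-p)**k``."""
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("every gene needs at least one AE site (k >= 1)")
    CleavageModel(p)  # validate p
    return 1.0 - (1.0 - p) ** k


def simulate_site_structures(
    n_genes: int,
    site_mean: float = 2.0,
    seed: int | np.random.Generator | None = None,
) -> list[GeneSiteStructure]:
    """Draw per-gene AE-site counts as ``1 + Poisson(site_mean)``.

    The +1 offset guarantees at least one cleavable site per gene; every
    simulated site is flagged unambiguous, matching the simulation protocol
    in which phi is computed from all sites.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if site_mean <= 0:
        raise ValueError(f"site_mean must be > 0, got {site_mean}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks = 1 + rng.poisson(site_mean, size=n_genes)
    return [GeneSiteStructure(f"g{i:05d}", int(k)) for i, k in enumerate(ks)]


# -- TSV serialization: gene_id <TAB> k <TAB> comma-separated 0/1 flags -----


def write_site_structures(structures: Iterable[GeneSiteStructure], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tk\tunambiguous\n")
        for s in structures:
            flags = ",".join("1" if f else "0" for f in s.unambiguous)
            fh.write(f"{s.gene_id}\t{s.k}\t{flags}\n")


def read_site_structures(path: str | Path) -> list[GeneSiteStructure]:
    path = Path(path)
    out: list[GeneSiteStructure] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "k", "unambiguous"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                gene_id, k_str, flag_str = line.rstrip("\n").split("\t")
                k = int(k_str)
                flags = tuple(c == "1" for c in flag_str.split(",")) if k else ()
            except Exception as exc:  # noqa: BLE001 - rewrap with location
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            out.append(GeneSiteStructure(gene_id, k, flags))
    return out
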