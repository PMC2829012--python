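"""Library file I/O, run metadata, and seeded fixture generation.

The single on-disk dialect for a tag library is a header-bearing TSV with
columns ``gene_id``, ``count`` and either ``phi`` (precomputed tag-formation
probability) or ``k`` (AE-site count, all sites unambiguous) together with a
cleavage probability supplied by the caller. Floats are written with their
shortest round-trip representation so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .estimators import TagLibrary, biased_from_true
from .samplers import PosteriorDraws
from .simulation_study import (
    BIN_GENE_COUNTS_L1000,
    BIN_GENE_COUNTS_L6178,
    ProtocolConfig,
    build_synthetic_m,
    simulate_library,
)
from .tagform import phi_from_site_counts

logger = logging.getLogger(__name__)

__all__ = [
    "read_library",
    "write_library",
    "write_draws",
    "make_fixture",
    "FIXTURE_KINDS",
]

FIXTURE_KINDS = ("toy3", "protocol_l1000", "protocol_l6178", "twofold_pair", "unequal_p_pair")


def read_library(path: str | Path, p: float | None = None) -> TagLibrary:
    """Read a tag library from TSV.

    With a ``phi`` column, values are used directly; with a ``k`` column a
    cleavage probability ``p`` must be given and phi is computed as
    ``1 - (1-p)**k``. Malformed rows, negative counts, phi outside (0, 1]
    and duplicate gene ids raise with the offending line number or id.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["gene_id", "count"] or header[2] not in ("phi", "k"):
            raise ValueError(
                f"{path}: expected header gene_id<TAB>count<TAB>phi|k, got {header}"
            )
        has_phi = header[2] == "phi"
        if not has_phi and p is None:
            raise ValueError(f"{path}: k column requires a cleavage probability p")
        gene_ids: list[str] = []
        counts: list[int] = []
        third: list[float] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            gid, cnt_s, val_s = parts[0], parts[1], parts[2]
            try:
                cnt = int(cnt_s)
                val = float(val_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count {cnt}")
            if has_phi and not (0.0 < val <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: phi={val} outside (0, 1]; gene {gid!r} is "
                    "unobservable or malformed and must be excluded"
                )
            gene_ids.append(gid)
            counts.append(cnt)
            third.append(val)
    if len(gene_ids) != len(set(gene_ids)):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene_id(s): {dupes}")
    if has_phi:
        phi = np.asarray(third)
    else:
        phi = phi_from_site_counts(np.asarray(third, dtype=int), p)
    return TagLibrary(gene_ids, np.asarray(counts), phi)


def write_library(lib: TagLibrary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tcount\tphi\n")
        for gid, cnt, ph in zip(lib.gene_ids, lib.t, lib.phi):
            fh.write(f"{gid}\t{cnt}\t{float(ph)!r}\n")


def write_draws(draws: PosteriorDraws, outdir: str | Path, meta: dict | None = None) -> None:
    """Write kept draws as a rectangular TSV (row = kept sweep) plus a YAML
    metadata sidecar (model, seed/config items passed in ``meta``, clamp
    counter)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = draws.gene_ids or [f"m{i}" for i in range(draws.m_draws.shape[1])]
    header = list(cols)
    arrays = [np.asarray(draws.m_draws, dtype=float)]
    for name, arr in draws.latent_draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            header.append(name)
            arrays.append(arr[:, None])
    data = np.hstack(arrays)
    with (outdir / "draws.tsv").open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    record = {
        "model": draws.model_tag,
        "n_kept": int(draws.m_draws.shape[0]),
        "n_clamped": int(draws.n_clamped),
    }
    record.update(meta or {})
    with (outdir / "metadata.yaml").open("w") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------


def _write_truth(path: Path, **payload) -> None:
    clean = {}
    for k, v in payload.items():
        if isinstance(v, np.ndarray):
            clean[k] = [float(x) for x in v]
        else:
            clean[k] = v
    with path.open("w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)


def make_fixture(kind: str, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Generate an on-disk scenario library (or pair) with a ground-truth
    sidecar. Deterministic: the same kind and seed produce byte-identical
    files."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    if kind == "toy3":
        m = np.array([0.5, 0.3, 0.2])
        p = 0.55
        k = np.array([1, 2, 3])
        phi = phi_from_site_counts(k, p)
        lib = simulate_library(m, phi, 50, seed=rng, gene_ids=["gA", "gB", "gC"])
        paths["library"] = outdir / "toy3.tsv"
        write_library(lib, paths["library"])
        paths["truth"] = outdir / "toy3.truth.yaml"
        _write_truth(paths["truth"], m=m, phi=phi, p=p, seed=seed, n_tags=50)
        return paths

    if kind in ("protocol_l1000", "protocol_l6178"):
        if kind == "protocol_l1000":
            config = ProtocolConfig(seed=seed)
        else:
            config = ProtocolConfig(
                l=6178, bin_gene_counts=BIN_GENE_COUNTS_L6178, seed=seed
            )
        m = build_synthetic_m(config, rng)
        ks = 1 + rng.poisson(config.site_mean, size=config.l)
        phi = phi_from_site_counts(ks, config.p)
        lib = simulate_library(m, phi, config.n_tags, seed=rng)
        paths["library"] = outdir / f"{kind}.tsv"
        write_library(lib, paths["library"])
        paths["truth"] = outdir / f"{kind}.truth.yaml"
        _write_truth(
            paths["truth"], m=m, phi=phi, p=config.p, seed=seed, n_tags=config.n_tags
        )
        return paths

    if kind == "twofold_pair":
        l = 100
        marked = 7
        base = np.full(l, 1.0 / l)
        m2 = base.copy()
        m2[marked] *= 2.0
        m2 /= m2.sum()
        ks = 1 + rng.poisson(2.0, size=l)
        phi = phi_from_site_counts(ks, 0.55)
        ids = [f"g{i:03d}" for i in range(l)]
        lib_a = simulate_library(base, phi, 30_000, seed=rng, gene_ids=ids)
        lib_b = simulate_library(m2, phi, 30_000, seed=rng, gene_ids=ids)
        paths["library_a"] = outdir / "twofold_a.tsv"
        paths["library_b"] = outdir / "twofold_b.tsv"
        write_library(lib_a, paths["library_a"])
        write_library(lib_b, paths["library_b"])
        paths["truth"] = outdir / "twofold.truth.yaml"
        _write_truth(
            paths["truth"],
            m_a=base, m_b=m2, phi=phi, p=0.55, seed=seed,
            marked_gene=ids[marked], n_tags=30_000,
        )
        return paths

    # unequal_p_pair: equal expression, different cleavage probabilities;
    # one marked gene whose tags derive from a site one position upstream.
    l = 100
    marked = 7
    m = np.full(l, 1.0 / l)
    p_a, p_b = 0.92, 0.96
    ids = [f"g{i:03d}" for i in range(l)]

    def _phi(p: float) -> np.ndarray:
        phi = np.full(l, p)  # 3'-most-site tags elsewhere
        phi[marked] = p * (1.0 - p)  # upstream tag (k = 1)
        return phi

    lib_a = simulate_library(m, _phi(p_a), 30_000, seed=rng, gene_ids=ids)
    lib_b = simulate_library(m, _phi(p_b), 30_000, seed=rng, gene_ids=ids)
    paths["library_a"] = outdir / "unequal_p_a.tsv"
    paths["library_b"] = outdir / "unequal_p_b.tsv"
    write_library(lib_a, paths["library_a"])
    write_library(lib_b, paths["library_b"])
    paths["truth"] = outdir / "unequal_p.truth.yaml"
    _write_truth(
        paths["truth"],
        m=m, p_a=p_a, p_b=p_b, phi_a=_phi(p_a), phi_b=_phi(p_b),
        marked_gene=ids[marked], k_upstream=1, seed=seed, n_tags=30_000,
    )
    return paths
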