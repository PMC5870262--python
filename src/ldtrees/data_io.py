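"""Genotype dataset, cluster map and result-table I/O.

Two on-disk dialects are supported for genotype data:

* ``matrix_tsv`` — a single TSV.  The header row carries three fixed
  columns (``snp_id``, ``chromosome``, ``position``) followed by one
  column per individual (the individual ids).  The first data row is a
  reserved ``PHENOTYPE`` row holding ``case``/``control`` labels; every
  following row is one SNP with genotype codes in ``{0,1,2,-1}`` where
  ``-1`` is the missing token.
* ``plink_text`` — classic PLINK ``.ped``/``.map`` text pair.  Genotypes
  are allele pairs ("0 0" = missing) and are collapsed on read to
  minor-allele counts; phenotype column uses 1 = control, 2 = case.

Cluster maps are TSVs with columns ``cluster_index``, ``snp_index``,
``snp_id``; association / importance tables are TSVs with columns
``snp_id``, ``score``, ``rank``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel genotype code for a missing call (the TSV dialect's token).
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class ParseError(ValueError):
    """Raised when an input file violates its dialect; names the line."""


@dataclass(frozen=True)
class SNPInfo:
    """Marker metadata: identifier, genomic coordinate, optional alleles.

    ``position_bp`` is 1-based, matching the ``.map`` convention; all
    physical-distance comparisons downstream are inclusive
    (``|pos_i - pos_j| <= delta``).
    """

    snp_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")


@dataclass
class GenotypeDataset:
    """SNP-by-individual genotype matrix with phenotype.

    Attributes
    ----------
    snps
        Per-SNP metadata, sorted by (chromosome, position).
    genotypes
        ``(n_snps, n_individuals)`` int8 array with entries in
        ``{0, 1, 2, MISSING}`` (minor-allele counts).
    phenotype
        Boolean array, ``True`` = case.
    individual_ids
        One id per column of ``genotypes``.
    """

    snps: list[SNPInfo]
    genotypes: np.ndarray
    phenotype: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        n_snps, n_ind = self.genotypes.shape
        if len(self.snps) != n_snps:
            raise ValueError("snps length does not match genotype rows")
        if len(self.phenotype) != n_ind or len(self.individual_ids) != n_ind:
            raise ValueError("phenotype/individual_ids length mismatch")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_id in dataset")
        self._sort_by_coordinate()

    def _sort_by_coordinate(self) -> None:
        order = sorted(
            range(len(self.snps)),
            key=lambda i: (self.snps[i].chromosome, self.snps[i].position_bp),
        )
        if order != list(range(len(self.snps))):
            self.snps = [self.snps[i] for i in order]
            self.genotypes = self.genotypes[order]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            snps=[self.snps[i] for i in idx],
            genotypes=self.genotypes[idx].copy(),
            phenotype=self.phenotype.copy(),
            individual_ids=list(self.individual_ids),
        )

    def subset_individuals(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = list(indices)
        return GenotypeDataset(
            snps=list(self.snps),
            genotypes=self.genotypes[:, idx].copy(),
            phenotype=self.phenotype[idx].copy(),
            individual_ids=[self.individual_ids[i] for i in idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snps == other.snps
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.individual_ids == other.individual_ids
        )


@dataclass
class ClusterMap:
    """Ordered partition of SNP indices into disjoint, non-empty clusters.

    ``provenance`` records whether the map came from contiguous blocks
    (T-Trees) or from layer-1 latent variables of an FLTM model (hybrid).
    """

    clusters: list[list[int]]
    provenance: str = "contiguous_blocks"
    n_snps: int = field(default=0)

    def __post_init__(self) -> None:
        if self.provenance not in ("contiguous_blocks", "fltm_layer1"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.clusters = [sorted(int(i) for i in c) for c in self.clusters]
        seen: set[int] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & set(c):
                raise ValueError("overlapping clusters")
            seen |= set(c)
        if self.n_snps == 0:
            self.n_snps = len(seen)
        if seen != set(range(self.n_snps)):
            raise ValueError(
                f"clusters must partition 0..{self.n_snps - 1}; "
                f"got {len(seen)} distinct indices"
            )

    def __len__(self) -> int:
        return len(self.clusters)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterMap):
            return NotImplemented
        return self.clusters == other.clusters and self.provenance == other.provenance


# ---------------------------------------------------------------------------
# matrix TSV dialect


def _write_matrix_tsv(ds: GenotypeDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchromosome\tposition\t" + "\t".join(ds.individual_ids) + "\n")
        pheno = ["case" if p else "control" for p in ds.phenotype]
        fh.write("PHENOTYPE\t.\t0\t" + "\t".join(pheno) + "\n")
        for snp, row in zip(ds.snps, ds.genotypes):
            fh.write(
                f"{snp.snp_id}\t{snp.chromosome}\t{snp.position_bp}\t"
                + "\t".join(str(int(g)) for g in row)
                + "\n"
            )


def _read_matrix_tsv(path: Path) -> GenotypeDataset:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: line 1: truncated matrix TSV")
    header = lines[0].split("\t")
    if header[:3] != ["snp_id", "chromosome", "position"]:
        raise ParseError(f"{path}: line 1: bad header {header[:3]}")
    individual_ids = header[3:]
    n_ind = len(individual_ids)

    ph_fields = lines[1].split("\t")
    if ph_fields[0] != "PHENOTYPE" or len(ph_fields) != 3 + n_ind:
        raise ParseError(f"{path}: line 2: expected PHENOTYPE row with {n_ind} labels")
    phenotype = []
    for tok in ph_fields[3:]:
        if tok not in ("case", "control"):
            raise ParseError(f"{path}: line 2: phenotype not binary: {tok!r}")
        phenotype.append(tok == "case")

    snps: list[SNPInfo] = []
    rows: list[list[int]] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 3 + n_ind:
            raise ParseError(f"{path}: line {lineno}: expected {3 + n_ind} fields")
        snp_id, chrom, pos = fields[0], fields[1], fields[2]
        if snp_id in seen_ids:
            raise ParseError(f"{path}: line {lineno}: duplicated snp_id {snp_id!r}")
        seen_ids.add(snp_id)
        try:
            position = int(pos)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: bad position {pos!r}") from None
        row = []
        for tok in fields[3:]:
            try:
                g = int(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: bad genotype token {tok!r}"
                ) from None
            if g not in _VALID_CODES:
                raise ParseError(f"{path}: line {lineno}: invalid genotype code {g}")
            row.append(g)
        snps.append(SNPInfo(snp_id=snp_id, chromosome=chrom, position_bp=position))
        rows.append(row)
    return GenotypeDataset(
        snps=snps,
        genotypes=np.array(rows, dtype=np.int8).reshape(len(snps), n_ind),
        phenotype=np.array(phenotype, dtype=bool),
        individual_ids=individual_ids,
    )


# ---------------------------------------------------------------------------
# PLINK text dialect (.ped / .map)


def _plink_paths(path: Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".ped":
        return p, p.with_suffix(".map")
    if p.suffix == ".map":
        return p.with_suffix(".ped"), p
    return p.with_suffix(".ped"), p.with_suffix(".map")


def _read_plink_text(path: Path) -> GenotypeDataset:
    ped_path, map_path = _plink_paths(path)
    snps: list[SNPInfo] = []
    seen: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns")
            chrom, snp_id, _cm, pos = fields[0], fields[1], fields[2], fields[3]
            if snp_id in seen:
                raise ParseError(f"{map_path}: line {lineno}: duplicated snp_id {snp_id!r}")
            seen.add(snp_id)
            snps.append(SNPInfo(snp_id=snp_id, chromosome=chrom, position_bp=int(pos)))
    n_snps = len(snps)

    individual_ids: list[str] = []
    phenotype: list[bool] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            iid, pheno = fields[1], fields[5]
            if pheno not in ("1", "2"):
                raise ParseError(
                    f"{ped_path}: line {lineno}: phenotype not binary (1/2): {pheno!r}"
                )
            individual_ids.append(iid)
            phenotype.append(pheno == "2")
            pairs = list(zip(fields[6::2], fields[7::2]))
            allele_rows.append(pairs)

    n_ind = len(individual_ids)
    genotypes = np.full((n_snps, n_ind), MISSING, dtype=np.int8)
    alleles_out: list[tuple[str, str] | None] = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(n_ind):
            for a in allele_rows[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise ParseError(f"{ped_path}: SNP {snps[j].snp_id}: more than 2 alleles")
        if not counts:
            alleles_out.append(None)
            continue
        # counted allele = minor; ties (MAF 0.5) broken lexicographically
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        minor = ordered[0][0]
        major = ordered[-1][0] if len(ordered) > 1 else minor
        alleles_out.append((major, minor))
        for i in range(n_ind):
            a1, a2 = allele_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            genotypes[j, i] = (a1 == minor) + (a2 == minor)

    snps = [
        SNPInfo(s.snp_id, s.chromosome, s.position_bp, alleles_out[j] if j < len(alleles_out) else None)
        for j, s in enumerate(snps)
    ]
    return GenotypeDataset(
        snps=snps,
        genotypes=genotypes,
        phenotype=np.array(phenotype, dtype=bool),
        individual_ids=individual_ids,
    )


def _write_plink_text(ds: GenotypeDataset, path: Path) -> None:
    ped_path, map_path = _plink_paths(path)
    with open(map_path, "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(ds.individual_ids):
            pheno = "2" if ds.phenotype[i] else "1"
            fields = [f"FAM{i + 1}", iid, "0", "0", "0", pheno]
            for j, s in enumerate(ds.snps):
                # default letters chosen so the reader's lexicographic
                # tie-break recovers the counted allele on MAF = 0.5 rows
                major, minor = s.alleles if s.alleles else ("B", "A")
                g = int(ds.genotypes[j, i])
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor] * g + [major] * (2 - g)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# public API


def read_dataset(path: str | Path, format: str = "matrix_tsv") -> GenotypeDataset:
    """Read a genotype dataset; ``format`` is ``matrix_tsv`` or ``plink_text``."""
    path = Path(path)
    if format == "matrix_tsv":
        return _read_matrix_tsv(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown format {format!r}")


def write_dataset(ds: GenotypeDataset, path: str | Path, format: str = "matrix_tsv") -> None:
    """Write a dataset so that :func:`read_dataset` recovers an equal one."""
    if ds.n_individuals == 0:
        raise ValueError("refusing to write a dataset with no individuals")
    path = Path(path)
    if format == "matrix_tsv":
        _write_matrix_tsv(ds, path)
    elif format == "plink_text":
        _write_plink_text(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cluster_map(path: str | Path, n_snps: int | None = None,
                     provenance: str = "contiguous_blocks") -> ClusterMap:
    """Read a cluster-map TSV (``cluster_index  snp_index  snp_id``).

    The partition invariant (every index 0..n_snps-1 exactly once) is
    enforced; a missing or repeated index raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"cluster_index", "snp_index"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    groups: dict[int, list[int]] = {}
    for ci, si in zip(df["cluster_index"], df["snp_index"]):
        groups.setdefault(int(ci), []).append(int(si))
    clusters = [groups[k] for k in sorted(groups)]
    cmap = ClusterMap(clusters=clusters, provenance=provenance)
    if n_snps is not None and cmap.n_snps != n_snps:
        raise ValueError(f"cluster map covers {cmap.n_snps} SNPs, expected {n_snps}")
    return cmap


def write_cluster_map(cmap: ClusterMap, path: str | Path,
                      snp_ids: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_index\tsnp_index\tsnp_id\n")
        for ci, cluster in enumerate(cmap.clusters):
            for si in cluster:
                sid = snp_ids[si] if snp_ids is not None else f"snp{si}"
                fh.write(f"{ci}\t{si}\t{sid}\n")


def write_scores(path: str | Path, snp_ids: Sequence[str],
                 scores: Sequence[float], ranks: Sequence[int]) -> None:
    """Write an importance / association table (snp_id, score, rank)."""
    with open(path, "w") as fh:
        fh.write("snp_id\tscore\trank\n")
        for sid, sc, rk in zip(snp_ids, scores, ranks):
            fh.write(f"{sid}\t{sc:.10g}\t{rk}\n")
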