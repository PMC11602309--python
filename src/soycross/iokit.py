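"""Readers/writers for the pipeline's on-disk formats and its core containers.

The pipeline works on panels of fully homozygous inbred lines, so a genotype
call at a biallelic site is a single code: 0 (reference), 1 (alternate) or
missing.  Residual heterozygous calls on input are treated as missing, not as
errors — RAD-seq panels of inbreds routinely contain a few percent of them.

Canonical dialects
------------------
* genotype TSV: ``marker_id  chromosome  pos_bp  pos_cM  <acc1> <acc2> ...``
  with calls ``0``/``1``/``NA``;
* phenotype CSV with header ``accession,environment,replicate,trait,value``;
* genetic-map TSV with header ``chromosome,length_cM[,marker_id,pos_cM]``;
* VCF v4.x (read only, biallelic SNPs) and GFF3 (read only, ``gene`` records).

Physical coordinates are 1-based (VCF/GFF3 convention); genetic positions are
centimorgans as floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

__all__ = [
    "GenotypePanel",
    "PhenotypeTable",
    "GeneticMap",
    "GeneAnnotation",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "apply_qc",
    "read_genetic_map",
    "read_gene_annotation",
]


@dataclass
class GenotypePanel:
    """Accessions x biallelic markers for a panel of homozygous lines.

    ``calls`` is an ``int8`` array of shape (n_accessions, n_markers) holding
    0 (reference), 1 (alternate) or -1 (missing).  ``markers`` has columns
    ``marker_id, chromosome, pos_bp, pos_cM`` and is sorted by
    (chromosome, pos_bp).
    """

    accession_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("accession ids are not unique")
        if self.calls.shape != (len(self.accession_ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.markers)} markers"
            )
        self._sort_canonical()

    def _sort_canonical(self) -> None:
        order = np.lexsort(
            (self.markers["pos_bp"].to_numpy(), self.markers["chromosome"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]
        else:
            self.markers = self.markers.reset_index(drop=True)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, over non-missing calls only."""
        calls = self.calls
        obs = calls >= 0
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(n_obs > 0, (calls == 1).sum(axis=0) / np.maximum(n_obs, 1), np.nan)
        return np.minimum(p_alt, 1.0 - p_alt)

    def missing_rate(self) -> np.ndarray:
        return (self.calls < 0).mean(axis=0)

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            accession_ids=list(self.accession_ids),
            markers=self.markers.loc[np.asarray(keep)].reset_index(drop=True),
            calls=self.calls[:, np.asarray(keep)],
        )


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records.

    ``data`` columns: accession, environment, replicate, trait, value.
    The (accession, environment, replicate, trait) key is unique.
    """

    data: pd.DataFrame

    KEY = ["accession", "environment", "replicate", "trait"]
    COLUMNS = KEY + ["value"]

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in self.COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table missing columns {missing_cols}")
        df = df[self.COLUMNS].copy()
        for c in self.KEY:
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        dup = df.duplicated(self.KEY, keep=False)
        if dup.any():
            keys = df.loc[dup, self.KEY].drop_duplicates().head(5).to_records(index=False)
            raise ValueError(f"duplicate phenotype keys: {list(keys)}")
        self.data = df.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def environments(self, trait: str | None = None) -> list[str]:
        df = self.data if trait is None else self.data[self.data["trait"] == trait]
        return sorted(df["environment"].unique())

    def accession_means(self, trait: str) -> pd.Series:
        """Per-accession mean over environments and replicates (env means first)."""
        df = self.data[(self.data["trait"] == trait) & self.data["value"].notna()]
        env_means = df.groupby(["accession", "environment"])["value"].mean()
        return env_means.groupby("accession").mean()


@dataclass
class GeneticMap:
    """Per-chromosome genetic lengths plus optional per-marker cM positions.

    Markers without an explicit cM position get ``pos_bp * rate_cM_per_Mb``
    (default 1 cM/Mb).
    """

    lengths_cM: dict[str, float]
    marker_cM: dict[str, float] = field(default_factory=dict)
    rate_cM_per_Mb: float = 1.0

    def genetic_pos(self, chromosome: str, pos_bp: int, marker_id: str | None = None) -> float:
        if marker_id is not None and marker_id in self.marker_cM:
            pos = self.marker_cM[marker_id]
        else:
            pos = pos_bp * self.rate_cM_per_Mb / 1e6
        length = self.lengths_cM.get(chromosome)
        if length is not None and pos > length + 1e-6:
            raise ValueError(
                f"marker {marker_id or ''} at {pos:.3f} cM beyond chromosome "
                f"{chromosome} length {length} cM"
            )
        return pos

    def length(self, chromosome: str) -> float:
        try:
            return self.lengths_cM[chromosome]
        except KeyError:
            raise KeyError(f"chromosome {chromosome!r} not in map") from None


@dataclass
class GeneAnnotation:
    """Gene records: gene_id, chromosome, start, end (1-based inclusive), strand, description."""

    data: pd.DataFrame

    COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "description"]

    def __post_init__(self) -> None:
        df = self.data[self.COLUMNS].copy()
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "gene_id"].head(3).tolist()
            raise ValueError(f"gene start > end for {bad}")
        self.data = df.reset_index(drop=True)


@dataclass
class QCReport:
    n_markers_in: int
    n_removed_missing: int
    n_removed_maf: int

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - self.n_removed_missing - self.n_removed_maf


# ---------------------------------------------------------------------------
# genotype I/O


def _read_genotypes_vcf(path: str) -> tuple[GenotypePanel, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows = []
    calls_cols: list[np.ndarray] = []
    n_het = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            warnings.warn(f"skipping non-biallelic-SNP site {var.CHROM}:{var.POS}")
            continue
        gt = np.asarray(var.genotype.array())[:, :2]
        col = np.full(len(accessions), MISSING, dtype=np.int8)
        known = (gt >= 0).all(axis=1)
        hom_ref = known & (gt == 0).all(axis=1)
        hom_alt = known & (gt == 1).all(axis=1)
        het = known & (gt[:, 0] != gt[:, 1])
        col[hom_ref] = 0
        col[hom_alt] = 1
        n_het += int(het.sum())
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((mid, var.CHROM, var.POS))
        calls_cols.append(col)
    markers = pd.DataFrame(rows, columns=["marker_id", "chromosome", "pos_bp"])
    markers["pos_cM"] = np.nan
    calls = (
        np.stack(calls_cols, axis=1) if calls_cols else np.empty((len(accessions), 0), np.int8)
    )
    return GenotypePanel(accessions, markers, calls), n_het


def _read_genotypes_tsv(path: str) -> tuple[GenotypePanel, int]:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    fixed = ["marker_id", "chromosome", "pos_bp", "pos_cM"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing columns {missing}")
    accessions = [c for c in df.columns if c not in fixed]
    calls = np.full((len(accessions), len(df)), MISSING, dtype=np.int8)
    for i, acc in enumerate(accessions):
        col = df[acc]
        ok = col.notna()
        calls[i, ok.to_numpy()] = col[ok].astype(int).to_numpy(dtype=np.int8)
    markers = df[fixed].copy()
    return GenotypePanel(accessions, markers, calls), 0


def read_genotypes(path: str, format: str = "tsv") -> GenotypePanel:
    """Read a genotype panel from VCF or the canonical TSV dialect.

    Heterozygous VCF calls are converted to missing (the panel is inbred by
    assumption); their count is reported via a warning.
    """
    if format == "vcf":
        panel, n_het = _read_genotypes_vcf(path)
        if n_het:
            warnings.warn(f"{n_het} heterozygous calls set to missing")
    elif format == "tsv":
        panel, _ = _read_genotypes_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return panel


def write_genotypes(panel: GenotypePanel, path: str) -> None:
    """Write the canonical genotype TSV dialect."""
    df = panel.markers.copy()
    for i, acc in enumerate(panel.accession_ids):
        col = panel.calls[i].astype(float)
        col[panel.calls[i] < 0] = np.nan
        df[acc] = pd.array(col, dtype="Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# phenotype I/O


def read_phenotypes(path: str) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# QC


def apply_qc(
    panel: GenotypePanel, max_missing: float = 0.2, min_maf: float = 0.01
) -> tuple[GenotypePanel, QCReport]:
    """Remove markers with missing rate > ``max_missing`` or MAF < ``min_maf``.

    MAF is computed over non-missing calls.  The accession set is unchanged.
    Idempotent: re-applying with the same thresholds removes nothing.
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    miss = panel.missing_rate()
    maf = panel.maf()
    fail_miss = miss > max_missing
    fail_maf = ~fail_miss & (np.isnan(maf) | (maf < min_maf))
    keep = ~(fail_miss | fail_maf)
    report = QCReport(
        n_markers_in=panel.n_markers,
        n_removed_missing=int(fail_miss.sum()),
        n_removed_maf=int(fail_maf.sum()),
    )
    return panel.subset_markers(keep), report


# ---------------------------------------------------------------------------
# map + annotation


def read_genetic_map(path: str, rate_cM_per_Mb: float = 1.0) -> GeneticMap:
    """Read the map TSV: one row per chromosome with its genetic length in cM,
    optionally repeated rows carrying explicit per-marker cM positions."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if "chromosome" not in df.columns or "length_cM" not in df.columns:
        raise ValueError("map TSV requires columns chromosome,length_cM")
    lengths = (
        df.dropna(subset=["length_cM"])
        .drop_duplicates("chromosome")
        .set_index("chromosome")["length_cM"]
        .astype(float)
        .to_dict()
    )
    marker_cM: dict[str, float] = {}
    if "marker_id" in df.columns and "pos_cM" in df.columns:
        mk = df.dropna(subset=["marker_id", "pos_cM"])
        marker_cM = dict(zip(mk["marker_id"].astype(str), mk["pos_cM"].astype(float)))
    return GeneticMap(lengths_cM=lengths, marker_cM=marker_cM, rate_cM_per_Mb=rate_cM_per_Mb)


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    rows = [{"chromosome": c, "length_cM": l} for c, l in sorted(gmap.lengths_cM.items())]
    pd.DataFrame(rows, columns=["chromosome", "length_cM"]).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str) -> GeneAnnotation:
    """Read ``gene`` records from a GFF3 file (id, coords, strand, description)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"seqid": str},
    )
    genes = df[df["type"] == "gene"].copy()

    def attr(s: str, key: str) -> str:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k.strip() == key:
                return v
        return ""

    out = pd.DataFrame(
        {
            "gene_id": genes["attributes"].map(lambda s: attr(s, "ID")),
            "chromosome": genes["seqid"],
            "start": genes["start"].astype(int),
            "end": genes["end"].astype(int),
            "strand": genes["strand"],
            "description": genes["attributes"].map(
                lambda s: attr(s, "description") or attr(s, "Note")
            ),
        }
    )
    return GeneAnnotation(out)
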