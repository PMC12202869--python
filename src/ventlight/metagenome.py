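"""Photosynthesis-apparatus gene completeness from read-alignment tables.

Scores, per metagenomic dataset, how complete each block of the oxygenic
photosynthesis machinery is (photosystems I/II, cytochrome b6f, the
photosynthetic electron-transport carriers, F-type ATPase, and the three
phycobilisome rod/core families), starting from DIAMOND/BLAST tabular
alignments of reads against a KEGG-orthology gene catalog.

The scoring pipeline is: per-read best hits (bitscore, ties shared) →
fractional read counts (a read shared by k genes contributes 1/k to each)
→ per-gene breadth of coverage (union of aligned subject intervals over
gene length) → presence at a coverage threshold (≥0.8 by default) →
per-category completeness fractions.  A far-red-light photoacclimation
(FaRLiP) probe and an ATPase-read community profile round out the module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "APPARATUS_CATEGORIES",
    "FARLIP_PROBES",
    "VENT_TYPES",
    "GeneCatalog",
    "HitRecord",
    "CompletenessMatrix",
    "load_default_catalog",
    "parse_hits",
    "best_hits",
    "aggregate_read_hits",
    "covered_fraction",
    "coverage_table",
    "gene_presence",
    "apparatus_completeness",
    "farlip_check",
    "community_profile",
    "export_matrix",
    "read_matrix",
]

APPARATUS_CATEGORIES = (
    "PSI", "PSII", "Cytb6f", "PET", "ATPase",
    "PBS_APC", "PBS_PC_PEC", "PBS_PE", "FaRLiP",
)

FARLIP_PROBES = ("apcD2", "apcD3", "apcD5")

#: Dataset classes: vent centre >350 °C (C1), <350 °C (C2), shallow
#: hydrothermal deposits (S), non-vent deep sea (N), oxidation zone (O),
#: subsurface rock (T1), enrichment cultures (T2).
VENT_TYPES = ("C1", "C2", "S", "N", "O", "T1", "T2")

_OUTFMT6_COLS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore")


@dataclass(frozen=True)
class GeneCatalog:
    """KEGG-orthology gene definitions grouped by apparatus category.

    ``entries`` maps gene_id → (symbol, category, length_aa).
    """

    entries: dict

    def __post_init__(self) -> None:
        for gid, (sym, cat, length) in self.entries.items():
            if cat not in APPARATUS_CATEGORIES:
                raise ValueError(f"{gid}: unknown category {cat!r}")
            if length <= 0:
                raise ValueError(f"{gid}: gene length must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def length(self, gene_id: str) -> int:
        return self.entries[gene_id][2]

    def symbol(self, gene_id: str) -> str:
        return self.entries[gene_id][0]

    def category(self, gene_id: str) -> str:
        return self.entries[gene_id][1]

    def genes_in(self, category: str) -> list[str]:
        if category not in APPARATUS_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [g for g, (_, c, _) in self.entries.items() if c == category]

    @classmethod
    def from_tsv(cls, path) -> "GeneCatalog":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene_id", "symbol", "category", "length_aa"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: catalog needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"{path}: duplicate gene_id {dup!r}")
        entries = {
            str(r.gene_id): (str(r.symbol), str(r.category), int(r.length_aa))
            for r in df.itertuples()
        }
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = [(g, s, c, n) for g, (s, c, n) in self.entries.items()]
        pd.DataFrame(rows, columns=["gene_id", "symbol", "category",
                                    "length_aa"]).to_csv(path, sep="\t", index=False)


def load_default_catalog() -> GeneCatalog:
    """The packaged synthetic stand-in catalog.

    Lists the gene symbols of the cyanobacterial photosynthetic apparatus
    (psaA–psaM, psbA–psbZ, pet, atp, apc/cpc/pec/cpe, and the FaRLiP
    probes apcD2/3/5) with plausible KO identifiers and lengths; it is a
    synthetic stand-in for a KEGG-derived catalog and is user-replaceable
    via :meth:`GeneCatalog.from_tsv`.
    """
    ref = resources.files("ventlight").joinpath("data/gene_catalog.tsv")
    with resources.as_file(ref) as p:
        return GeneCatalog.from_tsv(p)


@dataclass(frozen=True)
class HitRecord:
    """One DIAMOND/BLAST tabular alignment row (subject = catalog gene)."""

    read_id: str
    gene_id: str
    percent_identity: float
    align_length: int
    bitscore: float
    subject_start: int
    subject_end: int

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            # minus-orientation row: normalize so start <= end
            s, e = self.subject_end, self.subject_start
            object.__setattr__(self, "subject_start", s)
            object.__setattr__(self, "subject_end", e)
        if self.subject_start < 1:
            raise ValueError("subject coordinates are 1-based (>= 1)")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


def parse_hits(path) -> list[HitRecord]:
    """Parse a 12-column BLAST/DIAMOND tabular (outfmt 6) file.

    Malformed rows raise a parse error naming the offending line number.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}")
            try:
                records.append(HitRecord(
                    read_id=fields[0],
                    gene_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    bitscore=float(fields[11]),
                ))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return records


def best_hits(records: list[HitRecord]) -> dict[str, list[HitRecord]]:
    """Per read, the record(s) with maximal bitscore.

    Ties are all retained: a read aligning equally well to k genes forms a
    shared-alignment set of size k.
    """
    by_read: dict[str, list[HitRecord]] = {}
    for rec in records:
        cur = by_read.get(rec.read_id)
        if cur is None or rec.bitscore > cur[0].bitscore:
            by_read[rec.read_id] = [rec]
        elif rec.bitscore == cur[0].bitscore:
            cur.append(rec)
    return by_read


def aggregate_read_hits(best: dict[str, list[HitRecord]]) -> dict[str, float]:
    """Fractional read counts per gene: a k-way shared read adds 1/k each.

    The total over all genes equals the number of reads with at least one
    retained hit (count conservation).
    """
    counts: dict[str, float] = {}
    for recs in best.values():
        genes = {r.gene_id for r in recs}
        w = 1.0 / len(genes)
        for g in genes:
            counts[g] = counts.get(g, 0.0) + w
    return counts


def covered_fraction(records: list[HitRecord], gene_length: int) -> float:
    """Breadth of coverage: union of subject intervals over gene length."""
    if gene_length <= 0:
        raise ValueError("gene length must be > 0")
    ivals = sorted((r.subject_start, min(r.subject_end, gene_length))
                   for r in records)
    covered = 0
    cur_s = cur_e = None
    for s, e in ivals:
        if e < s:
            continue
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return min(1.0, covered / gene_length)


def coverage_table(hits_by_dataset: dict[str, list[HitRecord]],
                   catalog: GeneCatalog,
                   library_sizes: dict[str, int]) -> pd.DataFrame:
    """Per (dataset, gene): fractional read hits, hits per million library
    reads, and breadth of coverage.

    Restricts to genes in the catalog; unknown subject ids are ignored.
    """
    rows = []
    for ds, records in hits_by_dataset.items():
        records = [r for r in records if r.gene_id in catalog.entries]
        best = best_hits(records)
        counts = aggregate_read_hits(best)
        by_gene: dict[str, list[HitRecord]] = {}
        for recs in best.values():
            for r in recs:
                by_gene.setdefault(r.gene_id, []).append(r)
        lib = library_sizes.get(ds, 0)
        for gene in catalog.gene_ids:
            hits = counts.get(gene, 0.0)
            cov = covered_fraction(by_gene.get(gene, []), catalog.length(gene))
            rows.append({
                "dataset": ds,
                "gene_id": gene,
                "read_hits": hits,
                "normalized_hits": hits * 1e6 / lib if lib else 0.0,
                "covered_fraction": cov,
            })
    return pd.DataFrame(rows)


def gene_presence(coverage: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Presence calls: covered_fraction >= threshold (boolean, dataset x gene)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    wide = coverage.pivot(index="dataset", columns="gene_id",
                          values="covered_fraction")
    return wide >= threshold


@dataclass(frozen=True)
class CompletenessMatrix:
    """Dataset × apparatus-category completeness fractions with metadata.

    ``values`` is a DataFrame (rows: dataset ids, columns: categories,
    cells in [0, 1]); ``meta`` maps dataset id → vent type.
    """

    values: pd.DataFrame
    meta: dict

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and ((v < 0) | (v > 1)).any():
            raise ValueError("completeness cells must lie in [0, 1]")

    def grouped(self) -> pd.DataFrame:
        """Rows sorted by vent type then dataset id, with a vent_type column."""
        df = self.values.copy().sort_index()
        df.insert(0, "vent_type", [self.meta.get(d, "?") for d in df.index])
        order = {t: i for i, t in enumerate(VENT_TYPES)}
        key = df["vent_type"].map(order).fillna(len(VENT_TYPES))
        return df.iloc[np.argsort(key.to_numpy(), kind="stable")]


def apparatus_completeness(presence: pd.DataFrame, catalog: GeneCatalog,
                           meta: dict | None = None,
                           categories: tuple = None) -> CompletenessMatrix:
    """Fraction of each category's catalog genes called present, per dataset."""
    if categories is None:
        categories = tuple(c for c in APPARATUS_CATEGORIES if c != "FaRLiP")
    cols = {}
    for cat in categories:
        genes = catalog.genes_in(cat)
        if not genes:
            raise ValueError(f"category {cat!r} has no genes in the catalog")
        have = [g for g in genes if g in presence.columns]
        if have:
            frac = presence[have].sum(axis=1) / len(genes)
        else:
            frac = pd.Series(0.0, index=presence.index)
        cols[cat] = frac
    values = pd.DataFrame(cols, index=presence.index)
    values.index.name = "dataset"
    return CompletenessMatrix(values=values, meta=dict(meta or {}))


def farlip_check(presence: pd.DataFrame, catalog: GeneCatalog) -> pd.Series:
    """Per dataset: is any far-red photoacclimation probe gene present?

    Probes are apcD2/apcD3/apcD5; they must exist in the catalog.
    """
    probe_ids = [g for g in catalog.gene_ids
                 if catalog.symbol(g) in FARLIP_PROBES]
    if len(probe_ids) < len(FARLIP_PROBES):
        missing = set(FARLIP_PROBES) - {catalog.symbol(g) for g in probe_ids}
        raise ValueError(f"catalog lacks FaRLiP probe genes: {sorted(missing)}")
    have = [g for g in probe_ids if g in presence.columns]
    if not have:
        return pd.Series(False, index=presence.index)
    return presence[have].any(axis=1)


def community_profile(atp_hits: dict[str, float]) -> tuple[dict[str, float], float]:
    """Relative abundances and Shannon index (natural log) from ATPase reads."""
    total = float(sum(atp_hits.values()))
    if any(v < 0 for v in atp_hits.values()):
        raise ValueError("read counts must be >= 0")
    if total <= 0:
        raise ValueError("need at least one positive read count")
    abundances = {sp: v / total for sp, v in atp_hits.items()}
    h = -sum(p * math.log(p) for p in abundances.values() if p > 0)
    return abundances, float(h)


def export_matrix(matrix: CompletenessMatrix, path) -> None:
    """Write the completeness matrix as TSV (and a JSON sidecar).

    Rows grouped by vent type; cells formatted to 3 decimals.  The TSV
    round-trips losslessly through :func:`read_matrix` at that precision.
    """
    path = Path(path)
    try:
        df = matrix.grouped()
        df.to_csv(path, sep="\t", float_format="%.3f")
        payload = {
            "categories": list(matrix.values.columns),
            "datasets": [
                {"dataset": ds, "vent_type": matrix.meta.get(ds, "?"),
                 "completeness": {c: round(float(matrix.values.loc[ds, c]), 3)
                                  for c in matrix.values.columns}}
                for ds in df.index
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(payload, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing completeness matrix to {path}: {exc}") from exc


def read_matrix(path) -> CompletenessMatrix:
    """Read a completeness matrix written by :func:`export_matrix`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except OSError as exc:
        raise OSError(f"failed reading completeness matrix from {path}: {exc}") from exc
    meta = {}
    if "vent_type" in df.columns:
        meta = df["vent_type"].to_dict()
        df = df.drop(columns=["vent_type"])
    df.index.name = "dataset"
    return CompletenessMatrix(values=df.astype(float), meta=meta)
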