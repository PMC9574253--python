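"""File formats and core containers.

Conventions used throughout the package:

* genotypes are stored as Alt-allele dosages in {0, 1, 2} with ``MISSING``
  (-1) as the missing sentinel;
* genomic coordinates are 1-based inclusive everywhere internally; BED
  input is converted at the boundary.  A single convention avoids
  off-by-one errors in the 10-kbp gene-proximity rule;
* markers without a physical position (e.g. unplaced "ChrNA" chip
  markers) carry ``pos == UNPLACED`` (-1); they stay in the matrix for
  association testing but are excluded from annotation and LD steps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1
UNPLACED = -1

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates its format."""


class ValidationError(ValueError):
    """Raised when data violates an internal invariant."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers with Alt-dosage calls and metadata.

    Parameters
    ----------
    sample_ids, marker_ids
        Unique text labels for rows and columns of ``calls``.
    calls
        ``(n_samples, n_markers)`` integer array; entries in {0, 1, 2}
        count Alt alleles, ``MISSING`` marks a failed call.
    chrom
        Per-marker chromosome label ("NA" allowed for unplaced markers).
    pos
        Per-marker 1-based position; ``UNPLACED`` when unknown.
    ref, alt
        Per-marker single-base alleles.
    breed, location
        Optional per-sample labels.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    breed: list[str] | None = None
    location: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match calls")
        if len(self.marker_ids) != m:
            raise ValidationError("marker_ids length does not match calls")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if arr.shape != (m,):
                raise ValidationError(f"{name} length does not match markers")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValidationError("calls must be in {0,1,2} or MISSING")
        if ((self.pos < 1) & (self.pos != UNPLACED)).any():
            raise ValidationError("positions must be >= 1 or UNPLACED")
        for side in (self.breed, self.location):
            if side is not None and len(side) != n:
                raise ValidationError("per-sample metadata length mismatch")

    # -- basic accessors -----------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def calls_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing entries."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            marker_ids=[self.marker_ids[i] for i in index],
            calls=self.calls[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        pick = lambda xs: [xs[i] for i in index] if xs is not None else None
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            calls=self.calls[index],
            breed=pick(self.breed),
            location=pick(self.location),
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        """Markers ordered by (chromosome, position); unplaced last."""
        unplaced = self.pos == UNPLACED
        order = np.lexsort((self.pos, np.where(unplaced, 1, 0),
                            np.asarray([str(c) for c in self.chrom])))
        return self.take_markers(order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and list(self.chrom) == list(other.chrom)
            and np.array_equal(self.pos, other.pos)
            and list(self.ref) == list(other.ref)
            and list(self.alt) == list(other.alt)
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, *, skip_non_biallelic: bool = True) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of the ALT allele; ``./.`` maps to MISSING.
    Multi-allelic or non-SNP records are skipped when
    ``skip_non_biallelic`` is true, rejected otherwise.  ``POS == 0``
    marks an unplaced marker (round-trip convention for chip markers
    without a physical position).
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids: list[str] = []
    rows = []
    chrom, pos, ref, alt = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if skip_non_biallelic:
                continue
            raise FormatError(f"non-biallelic-SNP record at {var.CHROM}:{var.POS}")
        gts = var.genotype.array()
        a = gts[:, :2]
        dose = np.where((a < 0).any(axis=1), MISSING, a.clip(min=0).sum(axis=1))
        rows.append(dose.astype(np.int16))
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        ids.append(vid)
        chrom.append(var.CHROM)
        pos.append(var.POS if var.POS >= 1 else UNPLACED)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate marker ids in VCF")
    calls = (np.vstack(rows).T if rows
             else np.empty((len(samples), 0), dtype=np.int16))
    return GenotypeMatrix(samples, ids, calls, np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(ref, dtype=object), np.array(alt, dtype=object))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal deterministic VCF 4.2 (markers sorted by position)."""
    g = geno.sorted_by_position()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(x) for x in g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j in range(g.n_markers):
            pos = 0 if g.pos[j] == UNPLACED else int(g.pos[j])
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.calls[:, j])
            fh.write(f"{g.chrom[j]}\t{pos}\t{g.marker_ids[j]}\t{g.ref[j]}\t"
                     f"{g.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------------
# PLINK text (PED/MAP)
# ----------------------------------------------------------------------

def read_plink_text(ped_path: str | os.PathLike,
                    map_path: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK text PED/MAP pair.

    Alleles are base letters; ``0 0`` is a missing genotype.  Ref/Alt
    orientation is resolved at read time: Alt is the minor allele, ties
    broken alphabetically (so the lexically later base becomes Ref).
    """
    markers = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"MAP line with {len(parts)} fields: {line!r}")
            chrom, mid, _, bp = parts[0], parts[1], parts[2], parts[3]
            bp = int(bp)
            markers.append((chrom, mid, bp if bp >= 1 else UNPLACED))
    m = len(markers)
    if len({mid for _, mid, _ in markers}) != m:
        raise ValidationError("duplicate marker ids in MAP")

    sample_ids: list[str] = []
    allele_rows = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"PED row has {len(parts)} fields, expected {6 + 2 * m}")
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    n = len(sample_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else \
        np.empty((0, m, 2), dtype=object)

    calls = np.full((n, m), MISSING, dtype=np.int16)
    ref = np.empty(m, dtype=object)
    alt = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        seen = sorted({a for a in col.ravel() if a != "0"})
        if any(a not in _BASES for a in seen):
            raise FormatError(f"non-base allele code at marker {markers[j][1]}")
        if len(seen) > 2:
            raise FormatError(f"more than two alleles at marker {markers[j][1]}")
        if not seen:
            ref[j], alt[j] = "A", "C"  # all-missing column; arbitrary fixed pair
            continue
        if len(seen) == 1:
            a_ref, a_alt = seen[0], None
        else:
            counts = {a: int((col == a).sum()) for a in seen}
            # Alt = minor allele; alphabetical on ties
            a_alt, a_ref = sorted(seen, key=lambda a: (counts[a], a))
            if counts[a_alt] == counts[a_ref]:
                a_alt, a_ref = sorted(seen)[0], sorted(seen)[1]
        ref[j] = a_ref
        alt[j] = a_alt if a_alt is not None else ("C" if a_ref != "C" else "T")
        present = (col != "0").all(axis=1)
        calls[present, j] = (col[present] == alt[j]).sum(axis=1)

    chrom = np.array([c for c, _, _ in markers], dtype=object)
    pos = np.array([p for _, _, p in markers], dtype=np.int64)
    ids = [mid for _, mid, _ in markers]
    return GenotypeMatrix(sample_ids, ids, calls, chrom, pos, ref, alt)


def write_plink_text(geno: GenotypeMatrix, ped_path: str | os.PathLike,
                     map_path: str | os.PathLike) -> None:
    """Write a PED/MAP pair (markers sorted by position)."""
    g = geno.sorted_by_position()
    with open(map_path, "w") as fh:
        for j in range(g.n_markers):
            pos = 0 if g.pos[j] == UNPLACED else int(g.pos[j])
            fh.write(f"{g.chrom[j]}\t{g.marker_ids[j]}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(g.n_markers):
                d = int(g.calls[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [g.alt[j]] * d + [g.ref[j]] * (2 - d)
            fh.write(" ".join(fields) + "\n")


# ----------------------------------------------------------------------
# Gene tables (BED / GFF3)
# ----------------------------------------------------------------------

def read_gene_table(path: str | os.PathLike, dialect: str = "BED") -> list[GeneModel]:
    """Read gene intervals from BED4+ (0-based half-open) or GFF3 (1-based).

    All intervals are normalised to the internal 1-based inclusive
    convention.
    """
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if dialect == "BED":
                if len(parts) < 4:
                    raise FormatError(f"BED line needs >=4 fields: {line!r}")
                chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneModel(name, chrom, start0 + 1, end0, strand))
            else:
                if len(parts) < 9:
                    raise FormatError(f"GFF3 line needs 9 fields: {line!r}")
                chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                name = attr.get("ID") or attr.get("Name")
                if name is None:
                    raise FormatError(f"GFF3 record without ID/Name: {line!r}")
                genes.append(GeneModel(name, chrom, int(start), int(end),
                                       strand if strand in "+-" else "."))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids in gene table")
    return genes


def write_gene_table_bed(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ----------------------------------------------------------------------
# Result tables
# ----------------------------------------------------------------------

GWAS_COLUMNS = ["SNP ID", "Chr", "Pos", "Ref", "Alt", "Effect", "Lod",
                "pvalue", "Status", "Gene"]
DIVERSITY_COLUMNS = ["Group", "No.", "Hexp", "Ia", "rbarD"]


def gwas_records_frame(records) -> pd.DataFrame:
    """Candidate-gene table: one row per marker, fixed column order."""
    rows = []
    for r in records:
        rows.append({
            "SNP ID": r.marker_id,
            "Chr": r.chrom if r.chrom != "NA" else "-",
            "Pos": "-" if r.pos == UNPLACED else f"{int(r.pos):,}",
            "Ref": r.ref,
            "Alt": r.alt,
            "Effect": f"{r.effect:.2f}",
            "Lod": f"{r.lod:.2f}",
            "pvalue": f"{r.pvalue:.2e}",
            "Status": r.status,
            "Gene": r.gene,
        })
    return pd.DataFrame(rows, columns=GWAS_COLUMNS)


def diversity_frame(summaries) -> pd.DataFrame:
    rows = [{
        "Group": s.group,
        "No.": s.n,
        "Hexp": f"{s.hexp:.3f}",
        "Ia": f"{s.ia:.3f}" if np.isfinite(s.ia) else "-",
        "rbarD": f"{s.rbar_d:.5f}" if np.isfinite(s.rbar_d) else "-",
    } for s in summaries]
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS)


def write_results_tables(gwas_records, diversity_summaries, outdir: str | os.PathLike,
                         newick: str | None = None) -> dict[str, str]:
    """Write the candidate-gene TSV, the diversity TSV and optionally a tree.

    Returns the mapping of logical name to written path.  Writers are
    deterministic: fixed column order and float formats.
    """
    os.makedirs(outdir, exist_ok=True)
    out = {}
    p = os.path.join(outdir, "gwas_candidates.tsv")
    gwas_records_frame(gwas_records).to_csv(p, sep="\t", index=False)
    out["gwas"] = p
    p = os.path.join(outdir, "diversity.tsv")
    diversity_frame(diversity_summaries).to_csv(p, sep="\t", index=False)
    out["diversity"] = p
    if newick is not None:
        p = os.path.join(outdir, "fst_nj.nwk")
        with open(p, "w") as fh:
            fh.write(newick.rstrip() + "\n")
        out["tree"] = p
    return out
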