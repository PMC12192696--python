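"""Readers, writers and converters for the three interchange formats.

Three on-disk representations circulate in an imputation workflow:

* **numeric** -- tab-separated 0/1/2/NA table, individuals as rows (the
  GAPIT numeric convention); the native input of the pipeline.
* **HapMap** -- marker-major text with 11 metadata columns and two-letter
  diploid genotype codes (``AA``/``AG``/``GG``/``NN``).
* **VCF 4.2** -- GT-only diploid records, read back through :mod:`cyvcf2`.

All converters are closed under round-tripping: composing them returns the
identity on calls and taxa order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    MarkerInfo,
    ParseError,
    ValidationError,
    default_markers,
)

HAPMAP_META_COLUMNS = [
    "rs#",
    "alleles",
    "chrom",
    "pos",
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panel",
    "QCcode",
]

#: Surrogate diploid encoding used when a marker's real alleles are unknown.
SURROGATE_CODE = {0: "AA", 1: "AG", 2: "GG", MISSING: "NN"}

_NA_TOKENS = {"NA", "N", "", "NAN", "NULL"}


# ---------------------------------------------------------------------------
# numeric format
# ---------------------------------------------------------------------------

def read_numeric(path: str | Path, markers_as_rows: bool = False) -> GenotypeMatrix:
    """Read a tab-separated numeric genotype file.

    Default layout: header row of marker names (first cell is a taxa-column
    label), then one row per individual: taxon ID followed by 0/1/2/NA
    tokens.  ``markers_as_rows=True`` accepts the transposed dialect
    (markers as rows, taxa in the header).
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    if markers_as_rows:
        df = df.T
    taxa = [str(t) for t in df.index]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValidationError(f"duplicate taxa in {path}: {dupes}")
    marker_names = [str(c) for c in df.columns]
    tokens = np.char.upper(np.char.strip(df.to_numpy(dtype=str)))
    calls = np.full(tokens.shape, np.int8(MISSING), dtype=np.int8)
    for tok, code in (("0", 0), ("1", 1), ("2", 2)):
        calls[tokens == tok] = code
    recognized = np.isin(tokens, ["0", "1", "2"] + sorted(_NA_TOKENS))
    if not recognized.all():
        i, j = np.argwhere(~recognized)[0]
        raise ParseError(
            f"invalid numeric genotype token {df.iat[i, j]!r} at row {i + 1}, col {j + 1}"
        )
    markers = [
        MarkerInfo(name=name, chrom="1", pos=j + 1) for j, name in enumerate(marker_names)
    ]
    return GenotypeMatrix(taxa, markers, calls)


def write_numeric(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a tab-separated numeric file."""
    with open(path, "w") as fh:
        fh.write("taxa\t" + "\t".join(mk.name for mk in gm.markers) + "\n")
        for i, taxon in enumerate(gm.taxa):
            row = ["NA" if c == MISSING else str(int(c)) for c in gm.calls[i]]
            fh.write(taxon + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# HapMap format
# ---------------------------------------------------------------------------

def numeric_to_hapmap(gm: GenotypeMatrix) -> pd.DataFrame:
    """Encode a genotype matrix as a marker-major HapMap table.

    When a marker's (major, minor) alleles are known, 0 maps to major/major,
    1 to major/minor and 2 to minor/minor.  Markers without allele labels
    use the surrogate A/G coding (0 -> "AA", 1 -> "AG", 2 -> "GG",
    missing -> "NN").
    """
    rows = []
    for j, mk in enumerate(gm.markers):
        if mk.alleles is not None:
            major, minor = mk.alleles
        else:
            major, minor = "A", "G"
        code = {
            0: major + major,
            1: major + minor,
            2: minor + minor,
            MISSING: "NN",
        }
        meta = {
            "rs#": mk.name,
            "alleles": f"{major}/{minor}",
            "chrom": mk.chrom,
            "pos": mk.pos,
            "strand": "+",
            "assembly#": "NA",
            "center": "NA",
            "protLSID": "NA",
            "assayLSID": "NA",
            "panel": "NA",
            "QCcode": "NA",
        }
        meta.update({taxon: code[int(c)] for taxon, c in zip(gm.taxa, gm.calls[:, j])})
        rows.append(meta)
    return pd.DataFrame(rows, columns=HAPMAP_META_COLUMNS + list(gm.taxa))


def hapmap_to_numeric(hm: pd.DataFrame) -> GenotypeMatrix:
    """Recode a HapMap table into additive 0/1/2 calls.

    The (major, minor) order is taken from the HapMap ``alleles`` metadata
    column when it is informative (a ``X/Y`` pair covering the observed
    alleles), which keeps numeric -> HapMap -> numeric an exact identity.
    Otherwise the major allele is the more frequent one among called
    genotypes, with frequency ties broken alphabetically.  ``NN`` (or any
    pair containing a non-ACGT character) becomes missing.
    """
    taxa = [c for c in hm.columns if c not in HAPMAP_META_COLUMNS]
    n, m = len(taxa), len(hm)
    calls = np.full((m, n), MISSING, dtype=np.int8)  # marker-major, transposed later
    markers: list[MarkerInfo] = []
    geno = hm[taxa].to_numpy(dtype=str)
    for j in range(m):
        counts: dict[str, int] = {}
        pairs = []
        for cell in geno[j]:
            cell = cell.strip().upper()
            if len(cell) != 2:
                raise ParseError(f"genotype cell {cell!r} at marker row {j} is not diploid")
            a, b = cell[0], cell[1]
            if a not in "ACGT" or b not in "ACGT":
                pairs.append(None)  # NN or half-missing -> MISSING
                continue
            pairs.append((a, b))
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        alleles = sorted(counts)
        name = str(hm.iloc[j]["rs#"]) if "rs#" in hm.columns else f"snp{j + 1}"
        if len(alleles) > 2:
            raise ValidationError(f"marker {name!r} has >2 alleles: {alleles}")
        declared = None
        if "alleles" in hm.columns:
            raw = str(hm.iloc[j]["alleles"]).strip().upper()
            if len(raw) == 3 and raw[1] == "/" and raw[0] != raw[2] and all(
                c in "ACGT" for c in (raw[0], raw[2])
            ):
                if set(alleles) <= {raw[0], raw[2]}:
                    declared = (raw[0], raw[2])
        if declared is not None:
            major, minor = declared
        elif not alleles:
            major, minor = "A", "G"
        elif len(alleles) == 1:
            major = alleles[0]
            minor = "G" if major != "G" else "A"
        else:
            # more frequent allele is major; ties break alphabetically
            a0, a1 = alleles
            major, minor = (a0, a1) if counts[a0] >= counts[a1] else (a1, a0)
        for i, pair in enumerate(pairs):
            if pair is None:
                continue
            dosage = (pair[0] != major) + (pair[1] != major)
            calls[j, i] = dosage
        chrom = str(hm.iloc[j]["chrom"]) if "chrom" in hm.columns else "1"
        pos = int(hm.iloc[j]["pos"]) if "pos" in hm.columns else j + 1
        markers.append(MarkerInfo(name=name, chrom=chrom, pos=pos, alleles=(major, minor)))
    return GenotypeMatrix(taxa, markers, calls.T.copy())


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    hm = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    hm.columns = [c.strip() for c in hm.columns]
    return hapmap_to_numeric(hm)


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    numeric_to_hapmap(gm).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def to_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT.

    REF is the major allele, ALT the minor (surrogate A/G when unknown);
    the additive call is the ALT-allele dosage, written unphased.
    """
    chroms = []
    for mk in gm.markers:
        if mk.chrom not in chroms:
            chroms.append(mk.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kbimpute\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.taxa)
            + "\n"
        )
        for j, mk in enumerate(gm.markers):
            major, minor = mk.alleles if mk.alleles is not None else ("A", "G")
            gts = "\t".join(_GT_CODE[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{mk.chrom}\t{mk.pos}\t{mk.name}\t{major}\t{minor}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def from_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a diploid GT-only VCF into a :class:`GenotypeMatrix`.

    The additive call is the ALT-allele dosage; half-missing genotypes
    (``0/.``) are normalized to missing.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    taxa = list(vcf.samples)
    markers: list[MarkerInfo] = []
    rows = []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValidationError(
                f"multi-allelic record {var.ID or var.POS} not supported (biallelic SNPs only)"
            )
        alt = var.ALT[0] if var.ALT else ("G" if var.REF != "G" else "A")
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(
            MarkerInfo(name=name, chrom=str(var.CHROM), pos=int(var.POS), alleles=(var.REF, alt))
        )
        row = np.full(len(taxa), MISSING, dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:  # any half-missing call -> MISSING
                continue
            row[i] = (a > 0) + (b > 0)
        rows.append(row)
    vcf.close()
    calls = np.vstack(rows).T.copy() if rows else np.empty((len(taxa), 0), dtype=np.int8)
    return GenotypeMatrix(taxa, markers, calls)


# ---------------------------------------------------------------------------
# reordering
# ---------------------------------------------------------------------------

def reorder_to_taxa(gm: GenotypeMatrix, taxa_order: Sequence[str]) -> GenotypeMatrix:
    """Permute individuals to match ``taxa_order`` exactly.

    ``taxa_order`` must be a permutation of ``gm.taxa``; the symmetric
    difference is reported otherwise.  Markers are untouched.
    """
    have, want = set(gm.taxa), set(taxa_order)
    if have != want or len(taxa_order) != len(gm.taxa):
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValidationError(
            f"taxa_order is not a permutation of gm.taxa (missing={missing}, extra={extra})"
        )
    index = {t: i for i, t in enumerate(gm.taxa)}
    perm = [index[t] for t in taxa_order]
    return GenotypeMatrix(list(taxa_order), list(gm.markers), gm.calls[perm, :].copy())
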