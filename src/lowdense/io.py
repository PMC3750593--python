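"""File input/output: VCF genotypes and haplotypes, TSV map/pedigree/traits.

VCF parsing uses cyvcf2.  Phased records ("|" separator) populate the
haplotype library; unphased records populate dosages only.  VCF writing
emits plain VCF 4.2 text so that round trips stay bit-exact on dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .data import (
    MISSING,
    UNKNOWN_CHROM,
    GenotypeMatrix,
    HaplotypeLibrary,
    MarkerMap,
    Pedigree,
    TraitRecords,
)

__all__ = [
    "VcfData",
    "read_vcf",
    "write_vcf",
    "read_marker_map",
    "write_marker_map",
    "read_pedigree",
    "read_traits",
    "load_dataset",
]


@dataclass
class VcfData:
    """Raw parse of one VCF: ids, markers, dosages, phase and haplotypes."""

    ids: list
    markers: list
    chromosome: list
    position_mb: np.ndarray
    dosage: np.ndarray          # (n, m) int8, MISSING for ./.
    phased: np.ndarray          # (n, m) bool
    allele_a: np.ndarray        # (n, m) int8 first written allele
    allele_b: np.ndarray        # (n, m) int8 second written allele

    def genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.ids, self.markers, self.dosage.copy())

    def marker_map(self) -> MarkerMap:
        return MarkerMap(
            self.markers,
            self.chromosome,
            self.position_mb,
            [c != UNKNOWN_CHROM for c in self.chromosome],
        )

    def haplotype_library(self, require_phased=None) -> HaplotypeLibrary:
        """Library from fully phased samples.

        `require_phased` lists individuals that must be phased at every
        called genotype; an unphased heterozygote there raises an error.
        Other individuals are included only if fully phased.
        """
        require = set(require_phased or [])
        lib = HaplotypeLibrary(self.markers)
        for i, ind in enumerate(self.ids):
            called = self.dosage[i] != MISSING
            # homozygotes are trivially phased regardless of separator
            het = called & (self.allele_a[i] != self.allele_b[i])
            ok = bool(np.all(self.phased[i][het]))
            if not ok:
                if ind in require:
                    raise ValueError(
                        f"individual {ind} has unphased heterozygous genotypes "
                        "but a phased haplotype library is required"
                    )
                continue
            pat = self.allele_a[i].copy()
            mat = self.allele_b[i].copy()
            pat[~called] = MISSING
            mat[~called] = MISSING
            lib.add(ind, pat, mat)
        return lib


def read_vcf(path) -> VcfData:
    """Parse a VCF into dosages, phase flags and written allele order."""
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    markers, chroms, pos = [], [], []
    dos_rows, ph_rows, a_rows, b_rows = [], [], [], []
    seen = set()
    for v in vcf:
        mid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}_{v.POS}"
        if mid in seen:
            raise ValueError(f"duplicate marker id in VCF: {mid}")
        seen.add(mid)
        markers.append(mid)
        chroms.append(v.CHROM)
        pos.append(v.POS / 1e6)
        gt = np.array(v.genotypes, dtype=object)  # rows: [a, b, phased]
        a = np.array([g[0] for g in gt], dtype=np.int8)
        b = np.array([g[1] for g in gt], dtype=np.int8)
        phased = np.array([bool(g[2]) for g in gt])
        miss = (a < 0) | (b < 0)
        d = np.where(miss, MISSING, a + b).astype(np.int8)
        a[miss] = MISSING
        b[miss] = MISSING
        dos_rows.append(d)
        ph_rows.append(phased)
        a_rows.append(a)
        b_rows.append(b)
    vcf.close()
    m = len(markers)
    shape = (len(ids), m)
    return VcfData(
        ids=ids,
        markers=markers,
        chromosome=chroms,
        position_mb=np.array(pos),
        dosage=np.array(dos_rows, dtype=np.int8).T.reshape(shape) if m else np.zeros(shape, np.int8),
        phased=np.array(ph_rows).T.reshape(shape) if m else np.zeros(shape, bool),
        allele_a=np.array(a_rows, dtype=np.int8).T.reshape(shape) if m else np.zeros(shape, np.int8),
        allele_b=np.array(b_rows, dtype=np.int8).T.reshape(shape) if m else np.zeros(shape, np.int8),
    )


def write_vcf(path, geno: GenotypeMatrix, mmap: MarkerMap, library: HaplotypeLibrary | None = None,
              provenance: dict | None = None) -> None:
    """Write genotypes (and phased haplotypes where available) as VCF 4.2.

    Individuals present in `library` are written phased ("|") from their
    haplotypes; others get unphased genotypes derived from dosage
    (heterozygotes as 0/1).  Unplaced markers are written on contig
    ``UN`` at consecutive dummy positions.  `provenance` optionally maps
    individual id -> per-marker code array emitted as FORMAT/PV.
    """
    chrom = mmap.chromosome
    pos = mmap.position_mb
    order = []
    for c in mmap.chromosomes():
        order.extend(mmap.chrom_order(c).tolist())
    unplaced = [i for i in range(len(mmap)) if not mmap.is_placed()[i]]
    order.extend(unplaced)
    contigs = mmap.chromosomes() + ([UNKNOWN_CHROM] if unplaced else [])
    has_pv = provenance is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=lowdense\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_pv:
            fh.write('##FORMAT=<ID=PV,Number=1,Type=String,Description='
                     '"Imputation provenance: OBS, PAT, LIB or FBK">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.ids) + "\n")
        geno_cols = geno.marker_indices(mmap.marker_ids)
        lib_cols = (
            {m: i for i, m in enumerate(library.markers)} if library is not None else {}
        )
        dummy = 1
        for j in order:
            mid = mmap.marker_ids[j]
            if j in unplaced:
                c, p = UNKNOWN_CHROM, dummy
                dummy += 1
            else:
                c, p = chrom[j], int(round(pos[j] * 1e6))
            gcol = geno.dosage[:, geno_cols[j]]
            fields = [c, str(p), mid, "A", "B", ".", "PASS", ".",
                      "GT:PV" if has_pv else "GT"]
            for i, ind in enumerate(geno.ids):
                d = gcol[i]
                gt = "./."
                if library is not None and ind in library and mid in lib_cols:
                    k = lib_cols[mid]
                    a = library.paternal(ind)[k]
                    b = library.maternal(ind)[k]
                    if a != MISSING and b != MISSING:
                        gt = f"{a}|{b}"
                    elif d != MISSING:
                        gt = _unphased(d)
                elif d != MISSING:
                    gt = _unphased(d)
                if has_pv:
                    pv = provenance.get(ind)
                    code = pv[j] if pv is not None else "."
                    gt = f"{gt}:{code}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def _unphased(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]


def read_marker_map(path) -> MarkerMap:
    """TSV with header: marker_id, chrom, pos_mb, known (0/1)."""
    t = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = {"marker_id", "chrom", "pos_mb", "known"}
    if not required.issubset(t.columns):
        raise ValueError(f"marker map requires columns {sorted(required)}")
    return MarkerMap(t["marker_id"], t["chrom"], t["pos_mb"], t["known"].astype(int) == 1)


def write_marker_map(path, mmap: MarkerMap) -> None:
    out = pd.DataFrame(
        {
            "marker_id": mmap.marker_ids,
            "chrom": mmap.chromosome,
            "pos_mb": mmap.position_mb,
            "known": mmap.position_known.astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    """TSV with header: id, sire, dam; '0' marks an unknown parent."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "sire", "dam"}
    if not required.issubset(t.columns):
        raise ValueError(f"pedigree requires columns {sorted(required)}")
    return Pedigree(list(t[["id", "sire", "dam"]].itertuples(index=False, name=None)))


def write_pedigree(path, ped: Pedigree) -> None:
    rows = [(i, ped.sire[i] or "0", ped.dam[i] or "0") for i in ped.order]
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, sep="\t", index=False)


def read_traits(path) -> TraitRecords:
    """TSV with header: id, trait, ebv, reliability [, debv]."""
    t = pd.read_csv(path, sep="\t", dtype={"id": str, "trait": str})
    return TraitRecords(t)


def load_dataset(
    genotype_vcf,
    marker_map=None,
    pedigree=None,
    traits=None,
    library_vcf=None,
    require_phased_library: bool = False,
):
    """Assemble a full dataset from files.

    Returns (GenotypeMatrix, MarkerMap, Pedigree | None, TraitRecords | None,
    HaplotypeLibrary | None).  When no map file is given, positions come
    from the VCF with ``position_known`` set to True.  A separate
    `library_vcf` of phased training genotypes populates the haplotype
    library; with ``require_phased_library`` every sample in it must be
    fully phased.
    """
    raw = read_vcf(genotype_vcf)
    geno = raw.genotype_matrix()
    mmap = read_marker_map(marker_map) if marker_map is not None else raw.marker_map()
    missing = set(geno.markers) - set(mmap.marker_ids)
    if missing:
        raise ValueError(f"{len(missing)} VCF markers absent from the marker map")
    ped = read_pedigree(pedigree) if pedigree is not None else None
    recs = read_traits(traits) if traits is not None else None
    lib = None
    if library_vcf is not None:
        lraw = read_vcf(library_vcf)
        if lraw.markers != geno.markers:
            warnings.warn("library VCF marker set differs from genotype VCF", stacklevel=2)
        lib = lraw.haplotype_library(
            require_phased=lraw.ids if require_phased_library else None
        )
    return geno, mmap, ped, recs, lib
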