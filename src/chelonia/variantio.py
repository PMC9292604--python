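"""VCF/BED I/O, GATK-style hard filters, coverage and indel-proximity
filters, callable-mask arithmetic and genomic windows.

Filter defaults follow common practice for single-individual resequencing of
non-model genomes: a site is removed when it is not a biallelic SNP, QUAL<60,
FS>60, QD<2, MQ<40, MQRankSum<-20 or ReadPosRankSum<-8; additionally when it
falls in a region of aberrant coverage (outside [mean/4, 4*mean]) or within
5 bp of an indel called with QUAL>60.  An INFO annotation that is absent does
not trigger its criterion (upstream callers emit rank-sum annotations only at
heterozygous sites).

Coordinates: VCF records are 1-based inclusive; masks/windows are 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CallableMask, GenotypeTable, ScaffoldGenotypes, Window

__all__ = [
    "VariantRecord",
    "DEFAULT_THRESHOLDS",
    "hard_filter",
    "filter_records",
    "coverage_filter",
    "indel_proximity_filter",
    "intersect_masks",
    "make_windows",
    "read_bed",
    "write_bed",
    "write_vcf",
    "read_vcf",
    "genotype_table_to_records",
    "read_genotype_table",
]

DEFAULT_THRESHOLDS = {
    "qual_min": 60.0,
    "fs_max": 60.0,
    "qd_min": 2.0,
    "mq_min": 40.0,
    "mqranksum_min": -20.0,
    "readposranksum_min": -8.0,
}

_INFO_KEYS = ("FS", "QD", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass
class VariantRecord:
    """One VCF record restricted to the fields the pipeline models."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    qual: float | None = None
    info: dict = field(default_factory=dict)
    genotypes: tuple = ()  # per sample, tuple of allele indices (-1 missing)
    depths: tuple = ()  # per sample DP
    filter: str = "PASS"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.qual is not None and self.qual < 0:
            raise ValueError("negative QUAL")

    @property
    def is_indel(self) -> bool:
        # length-changing variants only; an MNP is not an indel
        return any(len(a) != len(self.ref) for a in self.alt)

    @property
    def is_biallelic_snp(self) -> bool:
        return len(self.alt) == 1 and len(self.ref) == 1 and len(self.alt[0]) == 1


def hard_filter(rec: VariantRecord, thresholds: dict | None = None) -> tuple[bool, list[str]]:
    """Evaluate every hard-filter criterion; return (keep, violated reasons).

    Criteria are independent, so the kept set does not depend on evaluation
    order.  Absent INFO annotations do not fire their criterion.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    reasons = []
    if not rec.is_biallelic_snp:
        reasons.append("not biallelic SNP")
    if rec.qual is not None and rec.qual < th["qual_min"]:
        reasons.append(f"QUAL<{th['qual_min']:g}")
    info = rec.info
    if "FS" in info and info["FS"] > th["fs_max"]:
        reasons.append(f"FS>{th['fs_max']:g}")
    if "QD" in info and info["QD"] < th["qd_min"]:
        reasons.append(f"QD<{th['qd_min']:g}")
    if "MQ" in info and info["MQ"] < th["mq_min"]:
        reasons.append(f"MQ<{th['mq_min']:g}")
    if "MQRankSum" in info and info["MQRankSum"] < th["mqranksum_min"]:
        reasons.append(f"MQRankSum<{th['mqranksum_min']:g}")
    if "ReadPosRankSum" in info and info["ReadPosRankSum"] < th["readposranksum_min"]:
        reasons.append(f"ReadPosRankSum<{th['readposranksum_min']:g}")
    return (not reasons, reasons)


def filter_records(
    records: list[VariantRecord], thresholds: dict | None = None, mode: str = "annotate"
) -> list[VariantRecord]:
    """Apply :func:`hard_filter` to a record list.

    ``mode="annotate"`` sets the FILTER column (semicolon-joined reasons,
    spaces replaced) and keeps every record; ``mode="drop"`` returns only the
    passing records.
    """
    if mode not in ("annotate", "drop"):
        raise ValueError("mode must be 'annotate' or 'drop'")
    out = []
    for rec in records:
        keep, reasons = hard_filter(rec, thresholds)
        if mode == "drop":
            if keep:
                out.append(rec)
        else:
            rec.filter = "PASS" if keep else ";".join(r.replace(" ", "_") for r in reasons)
            out.append(rec)
    return out


def coverage_filter(
    depth_profile: np.ndarray, mean_depth: float, k: float = 4.0
) -> np.ndarray:
    """Maximal half-open intervals of aberrant coverage.

    A base at 0-based index i is excluded when ``depth[i] > k*mean`` or
    ``depth[i] < mean/k`` (both bounds configurable through ``k``; the upper
    and lower factors are symmetric on a log scale).
    """
    depth = np.asarray(depth_profile, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth profile")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    bad = (depth > k * mean_depth) | (depth < mean_depth / k)
    return _bool_to_intervals(bad)


def _bool_to_intervals(bad: np.ndarray) -> np.ndarray:
    padded = np.concatenate([[False], bad, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return np.column_stack([starts, ends]).astype(np.int64)


def indel_proximity_filter(
    records: list[VariantRecord], radius: int = 5, indel_qual_min: float = 60.0
) -> list[VariantRecord]:
    """Drop SNPs within ``radius`` bp of a confidently called indel.

    Only indels with QUAL > ``indel_qual_min`` trigger removal; indel records
    themselves are not returned.  Input must be sorted by (scaffold, pos).
    """
    last = None
    for rec in records:
        key = (rec.scaffold, rec.pos)
        if last is not None and rec.scaffold == last[0] and rec.pos < last[1]:
            raise ValueError("records must be sorted by scaffold and position")
        last = key

    indel_pos: dict[str, list[int]] = {}
    for rec in records:
        if rec.is_indel and rec.qual is not None and rec.qual > indel_qual_min:
            indel_pos.setdefault(rec.scaffold, []).append(rec.pos)

    kept = []
    for rec in records:
        if rec.is_indel:
            continue
        positions = indel_pos.get(rec.scaffold)
        if positions:
            arr = np.asarray(positions)
            i = np.searchsorted(arr, rec.pos)
            near = False
            for j in (i - 1, i):
                if 0 <= j < len(arr) and abs(int(arr[j]) - rec.pos) <= radius:
                    near = True
            if near:
                continue
        kept.append(rec)
    return kept


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def intersect_masks(masks: list[CallableMask]) -> CallableMask:
    """Exact interval intersection of one or more callable masks."""
    if not masks:
        raise ValueError("need at least one mask")
    names = set(masks[0].intervals)
    for m in masks[1:]:
        names &= set(m.intervals)
    out = {}
    for name in sorted(names):
        iv = masks[0].intervals[name]
        for m in masks[1:]:
            iv = _intersect_two(iv, m.intervals[name])
            if iv.size == 0:
                break
        out[name] = iv
    return CallableMask(out)


def make_windows(layout, size: int, min_scaffold: int = 0) -> list[Window]:
    """Tile scaffolds into non-overlapping windows of ``size`` bp.

    Scaffolds shorter than ``min_scaffold`` are skipped entirely; a trailing
    partial window is retained and flagged ``partial`` so statistics can
    normalize by callable span rather than discarding sequence.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if hasattr(layout, "scaffolds") and not isinstance(layout, dict):
        lengths = dict(layout.scaffolds)
    else:
        lengths = dict(layout)
    windows = []
    for name, length in lengths.items():
        if length < min_scaffold:
            continue
        for start in range(0, length, size):
            end = min(start + size, length)
            windows.append(Window(name, start, end, partial=(end - start) < size))
    return windows


# ---------------------------------------------------------------------------
# BED / VCF serialization


def read_bed(path) -> CallableMask:
    intervals: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            name, start, end = line.split("\t")[:3]
            intervals.setdefault(name, []).append((int(start), int(end)))
    return CallableMask({k: np.array(sorted(v), dtype=np.int64) for k, v in intervals.items()})


def write_bed(mask: CallableMask, path) -> None:
    with open(path, "w") as fh:
        for name, iv in mask.intervals.items():
            for start, end in iv:
                fh.write(f"{name}\t{start}\t{end}\n")


def _fmt_float(x) -> str:
    return f"{float(x):g}"


def write_vcf(
    path,
    records: list[VariantRecord],
    samples: list[str],
    contigs: dict[str, int] | None = None,
    phased: bool = True,
) -> None:
    """Write VCF 4.2 text for a list of records."""
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chelonia\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key in _INFO_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + samples
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            info = (
                ";".join(f"{k}={_fmt_float(v)}" for k, v in rec.info.items() if k in _INFO_KEYS)
                or "."
            )
            qual = "." if rec.qual is None else _fmt_float(rec.qual)
            fields = [
                rec.scaffold,
                str(rec.pos),
                ".",
                rec.ref,
                ",".join(rec.alt) if rec.alt else ".",
                qual,
                rec.filter or "PASS",
                info,
                "GT:DP",
            ]
            for si in range(len(samples)):
                gt = rec.genotypes[si] if si < len(rec.genotypes) else ()
                gt_str = sep.join("." if a < 0 else str(a) for a in gt) if gt else "."
                dp = rec.depths[si] if si < len(rec.depths) else "."
                fields.append(f"{gt_str}:{dp}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF into :class:`VariantRecord` objects via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        info = {}
        for key in _INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        gts = tuple(tuple(int(a) for a in g[:-1]) for g in v.genotypes) if samples else ()
        try:
            dp = v.format("DP")
            depths = tuple(int(x) for x in dp[:, 0]) if dp is not None else ()
        except Exception:
            depths = ()
        records.append(
            VariantRecord(
                scaffold=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alt=tuple(v.ALT),
                qual=None if v.QUAL is None else float(v.QUAL),
                info=info,
                genotypes=gts,
                depths=depths,
                filter=v.FILTER or "PASS",
            )
        )
    return records, samples


def genotype_table_to_records(g: GenotypeTable) -> list[VariantRecord]:
    records = []
    for name, sg in g.scaffolds.items():
        for i in range(sg.n_sites):
            records.append(
                VariantRecord(
                    scaffold=name,
                    pos=int(sg.pos[i]),
                    ref=str(sg.ref[i]),
                    alt=(str(sg.alt[i]),),
                    qual=None if sg.qual is None else float(sg.qual[i]),
                    genotypes=tuple(tuple(int(a) for a in sg.gt[i, s]) for s in range(len(g.samples))),
                    depths=() if sg.depth is None else tuple(int(d) for d in sg.depth[i]),
                )
            )
    return records


def write_genotype_table_vcf(g: GenotypeTable, path) -> None:
    write_vcf(
        path,
        genotype_table_to_records(g),
        g.samples,
        contigs=dict(g.scaffold_lengths),
        phased=g.phased,
    )


def read_genotype_table(path, contigs: dict[str, int] | None = None) -> GenotypeTable:
    """Read a VCF of biallelic SNPs into a :class:`GenotypeTable`.

    Non-biallelic or non-SNP records are skipped.  ``contigs`` overrides the
    scaffold lengths when the header lacks contig lines.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    if contigs:
        lengths.update(contigs)
    data: dict[str, dict[str, list]] = {}
    ploidy = 2
    phased = True
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        d = data.setdefault(v.CHROM, {"pos": [], "ref": [], "alt": [], "gt": [], "dp": [], "qual": []})
        d["pos"].append(v.POS)
        d["ref"].append(v.REF)
        d["alt"].append(v.ALT[0])
        site_gt = []
        for g in v.genotypes:
            alleles = g[:-1]
            ploidy = len(alleles)
            phased = bool(g[-1]) if len(alleles) > 1 else phased
            site_gt.append(alleles)
        d["gt"].append(site_gt)
        dp = v.format("DP")
        d["dp"].append([int(x) for x in dp[:, 0]] if dp is not None else [0] * len(samples))
        d["qual"].append(0.0 if v.QUAL is None else float(v.QUAL))
    scaffolds = {}
    for name, d in data.items():
        scaffolds[name] = ScaffoldGenotypes(
            pos=np.array(d["pos"], dtype=np.int64),
            ref=np.array(d["ref"], dtype="U1"),
            alt=np.array(d["alt"], dtype="U1"),
            gt=np.array(d["gt"], dtype=np.int8),
            depth=np.array(d["dp"], dtype=np.int32),
            qual=np.array(d["qual"]),
        )
    for name in scaffolds:
        lengths.setdefault(name, int(scaffolds[name].pos[-1]) if scaffolds[name].n_sites else 0)
    return GenotypeTable(
        samples=samples,
        scaffolds=scaffolds,
        scaffold_lengths=lengths,
        ploidy=ploidy,
        phased=phased,
    )
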