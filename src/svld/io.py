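"""Readers and writers for the standard formats the pipeline touches.

VCF 4.2 is the exchange format for variants (symbolic SV ALTs with
SVTYPE/END/CIPOS/CIEND, phased GT for haplotype panels); per-sample read
depth comes as BED4 windows (mosdepth-style); array manifests and genome
tables are plain TSV.  All conversions between the internal 0-based
half-open convention and the 1-based VCF convention happen here and only
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .datamodel import (
    MISSING,
    DepthProfile,
    GenomeTable,
    HaplotypePanel,
    VariantRecord,
    VType,
)

logger = logging.getLogger(__name__)


class VcfFormatError(ValueError):
    """Raised for malformed VCF content that cannot be skipped."""


@dataclass
class RejectedRecord:
    """A VCF record excluded from the parse, with its 1-based line number."""

    line: int
    vcf_id: str
    reason: str


@dataclass
class VcfData:
    """Result of :func:`read_vcf`."""

    records: list[VariantRecord]
    samples: list[str]
    panel: HaplotypePanel | None
    genome: GenomeTable | None
    rejected: list[RejectedRecord] = field(default_factory=list)


_SV_ALTS = {"<DEL>": VType.DEL, "<DUP>": VType.DUP, "<INV>": VType.INV, "<BND>": VType.BND}


def _info_get(rec, key: str, default):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def read_vcf(
    path: str | Path,
    want_panel: bool = False,
    populations: Mapping[str, str] | None = None,
) -> VcfData:
    """Read a VCF 4.2 file into variant records (and optionally a panel).

    1-based POS becomes the 0-based internal ``start``; the INFO END of
    DEL/DUP/INV is honored as the (exclusive) internal ``end``.  Symbolic-ALT
    records without SVTYPE and multi-allelic SNP rows are collected in
    ``rejected`` rather than raising.  When ``want_panel`` is set, every GT
    must be phased and non-missing; ``populations`` maps sample id to a
    population label (default: a single population ``"pop"``).
    """
    path = str(path)
    records: list[VariantRecord] = []
    rejected: list[RejectedRecord] = []
    hap_cols: list[np.ndarray] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        with open(path) as fh:  # raw header size, for faithful line numbers
            header_lines = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
        genome = None
        if vf.header.contigs:
            lengths = {
                name: c.length
                for name, c in vf.header.contigs.items()
                if c.length is not None
            }
            if lengths:
                genome = GenomeTable(lengths=lengths)
        for idx, rec in enumerate(vf):
            line = header_lines + idx + 1
            rid = rec.id or f"{rec.chrom}_{rec.pos}"
            if rec.alts is None or len(rec.alts) == 0:
                rejected.append(RejectedRecord(line, rid, "no ALT allele"))
                continue
            if len(rec.alts) > 1:
                rejected.append(RejectedRecord(line, rid, "multi-allelic record"))
                continue
            alt = rec.alts[0]
            symbolic = alt.startswith("<")
            if symbolic:
                svtype = _info_get(rec, "SVTYPE", None)
                if svtype is None:
                    rejected.append(
                        RejectedRecord(line, rid, "symbolic ALT without SVTYPE")
                    )
                    continue
                try:
                    vtype = VType(svtype)
                except ValueError:
                    rejected.append(
                        RejectedRecord(line, rid, f"unknown SVTYPE {svtype!r}")
                    )
                    continue
                start = rec.start
                end = start + 1 if vtype is VType.BND else rec.stop
            else:
                if len(rec.ref) != 1 or len(alt) != 1:
                    rejected.append(RejectedRecord(line, rid, "indel ALT not supported"))
                    continue
                vtype = VType.SNP
                start, end = rec.start, rec.start + 1
            ci_start = tuple(_info_get(rec, "CIPOS", (0, 0)))
            ci_end = tuple(_info_get(rec, "CIEND", (0, 0)))
            callers = _info_get(rec, "CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            geno = np.full(len(samples), MISSING, dtype=np.int8)
            for i, sample in enumerate(samples):
                sd = rec.samples[sample]
                gt = sd.get("GT", (None,))
                if gt is None or all(a is None for a in gt):
                    if want_panel:
                        raise VcfFormatError(
                            f"line {line}: missing GT for {sample} "
                            "but a phased panel was requested"
                        )
                    continue
                if len(gt) != 2 or any(a not in (0, 1) for a in gt):
                    raise VcfFormatError(
                        f"line {line}: malformed GT {gt!r} for sample {sample}"
                    )
                if want_panel and not sd.phased:
                    raise VcfFormatError(
                        f"line {line}: unphased GT for {sample} "
                        "but a phased panel was requested"
                    )
                geno[i] = gt[0] + gt[1]
            if want_panel:
                col = np.empty(2 * len(samples), dtype=np.uint8)
                for i, sample in enumerate(samples):
                    gt = rec.samples[sample]["GT"]
                    col[2 * i], col[2 * i + 1] = gt
                hap_cols.append(col)
            records.append(
                VariantRecord(
                    id=rid,
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    vtype=vtype,
                    genotypes=geno,
                    ci_start=(int(ci_start[0]), int(ci_start[1])),
                    ci_end=(int(ci_end[0]), int(ci_end[1])),
                    caller_support=frozenset(callers),
                    ref=rec.ref,
                    alt=alt,
                )
            )
    panel = None
    if want_panel:
        pops = [
            (populations or {}).get(s, "pop") for s in samples
        ]
        panel = HaplotypePanel(
            alleles=np.column_stack(hap_cols)
            if hap_cols
            else np.empty((2 * len(samples), 0), dtype=np.uint8),
            sample_ids=samples,
            variants=records,
            populations=pops,
        )
    return VcfData(records=records, samples=samples, panel=panel, genome=genome, rejected=rejected)


def _vcf_header(
    samples: Sequence[str], genome: GenomeTable | None
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    if genome is not None:
        for chrom in genome.chromosomes:
            header.contigs.add(chrom, length=genome.lengths[chrom])
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">'
    )
    header.add_line(
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">'
    )
    header.add_line(
        '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="Confidence interval around END">'
    )
    header.add_line(
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str] | None = None,
    panel: HaplotypePanel | None = None,
    genome: GenomeTable | None = None,
) -> None:
    """Write records (sorted by chrom, start) as a canonical VCF 4.2 file.

    SVs are emitted with symbolic ALTs and SVTYPE/END/CIPOS/CIEND INFO keys;
    when ``panel`` is given, its phased haplotypes are written as ``a|b`` GT
    fields, otherwise dosage genotypes are written unphased (dosage 1 as
    ``0/1``) with ``./.`` for missing.
    """
    order = [(r.chrom, r.start) for r in records]
    if order != sorted(order):
        raise ValueError("records must be sorted by (chrom, start) before writing")
    if panel is not None:
        samples = panel.sample_ids
        col_of = {id(v): j for j, v in enumerate(panel.variants)}
    if samples is None:
        n = max((len(r.genotypes) for r in records if r.genotypes is not None), default=0)
        samples = [f"s{i}" for i in range(n)]
    header = _vcf_header(samples, genome)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            symbolic = r.vtype is not VType.SNP
            alleles = ("N", f"<{r.vtype.value}>") if symbolic else (r.ref, r.alt or "A")
            kwargs = {}
            if symbolic:
                kwargs["stop"] = r.start + 1 if r.vtype is VType.BND else r.end
            rec = out.new_record(
                contig=r.chrom, start=r.start, alleles=alleles, id=r.id, **kwargs
            )
            if symbolic:
                rec.info["SVTYPE"] = r.vtype.value
                if r.ci_start != (0, 0):
                    rec.info["CIPOS"] = r.ci_start
                if r.ci_end != (0, 0):
                    rec.info["CIEND"] = r.ci_end
            if r.caller_support:
                rec.info["CALLERS"] = tuple(sorted(r.caller_support))
            if panel is not None:
                j = col_of[id(r)]
                col = panel.alleles[:, j]
                for i, s in enumerate(samples):
                    rec.samples[s]["GT"] = (int(col[2 * i]), int(col[2 * i + 1]))
                    rec.samples[s].phased = True
            elif r.genotypes is not None:
                for i, s in enumerate(samples):
                    d = int(r.genotypes[i])
                    if d == MISSING:
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[d]
            out.write(rec)


def read_depth_bed(path: str | Path, sample: str | None = None) -> DepthProfile:
    """Read one sample's mosdepth-style window BED (chrom, start, end, cov).

    Windows must share one size and not overlap; gaps are zero-filled (a
    warning logs the count).  The sample name defaults to the file stem.
    """
    path = Path(path)
    sample = sample or path.stem
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "coverage"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"{path}: empty depth BED")
    sizes = (df["end"] - df["start"]).unique()
    if len(sizes) != 1:
        raise ValueError(f"{path}: inconsistent window sizes {sorted(sizes)}")
    window = int(sizes[0])
    if (df["start"] % window).any():
        raise ValueError(f"{path}: windows not aligned to the window size")
    data: dict[str, np.ndarray] = {}
    n_gaps = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        idx = (grp["start"] // window).to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"{path}: overlapping windows on {chrom}")
        vec = np.zeros(int(idx[-1]) + 1, dtype=np.float64)
        vec[idx] = grp["coverage"].to_numpy()
        n_gaps += len(vec) - len(idx)
        data[chrom] = vec
    if n_gaps:
        logger.warning("%s: %d missing windows zero-filled", path, n_gaps)
    profile = DepthProfile(window_size=window, data={sample: data})
    profile.n_gap_windows = n_gaps  # type: ignore[attr-defined]
    return profile


def read_depth_beds(paths: Mapping[str, str | Path], window_size: int | None = None) -> DepthProfile:
    """Read one depth BED per sample into a combined profile."""
    combined: dict[str, dict[str, np.ndarray]] = {}
    window = window_size
    for sample, p in paths.items():
        prof = read_depth_bed(p, sample=sample)
        if window is None:
            window = prof.window_size
        elif window != prof.window_size:
            raise ValueError("window sizes differ between samples")
        combined[sample] = prof.data[sample]
    if window is None:
        raise ValueError("no depth files given")
    return DepthProfile(window_size=window, data=combined)


def write_depth_bed(profile: DepthProfile, sample: str, path: str | Path) -> None:
    """Write one sample of a depth profile as BED4 windows."""
    w = profile.window_size
    rows = []
    for chrom, vec in profile.data[sample].items():
        starts = np.arange(len(vec)) * w
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + w, "coverage": vec}
            )
        )
    pd.concat(rows).to_csv(path, sep="\t", header=False, index=False)


def read_array_manifest(path: str | Path) -> set[tuple[str, int]]:
    """Read a two-column (chrom, 1-based position) marker manifest.

    Returns internal 0-based positions; duplicates are dropped (count
    logged).  Non-integer positions raise.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos"], dtype={"chrom": str},
        comment="#",
    )
    if df.empty:
        return set()
    try:
        pos = df["pos"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer position in manifest") from exc
    pairs = list(zip(df["chrom"], pos - 1))
    unique = set(pairs)
    dups = len(pairs) - len(unique)
    if dups:
        logger.info("%s: %d duplicate manifest positions removed", path, dups)
    return unique


def write_array_manifest(sites: Iterable[tuple[str, int]], path: str | Path) -> None:
    """Write (chrom, internal 0-based position) sites as a 1-based TSV."""
    rows = sorted((c, p + 1) for c, p in sites)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genome_table(path: str | Path) -> GenomeTable:
    """Read a genome table TSV: chrom, length[, autosome flag 0/1]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    lengths = dict(zip(df[0], df[1].astype(int)))
    if len(lengths) != len(df):
        raise ValueError(f"{path}: duplicate chromosome names")
    autosome = (
        dict(zip(df[0], df[2].astype(bool))) if df.shape[1] > 2 else {}
    )
    return GenomeTable(lengths=lengths, autosome=autosome)


def write_genome_table(genome: GenomeTable, path: str | Path) -> None:
    rows = [
        (c, genome.lengths[c], int(genome.autosome[c])) for c in genome.chromosomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a sample -> population TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_population_table(populations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(populations.items())).to_csv(
        path, sep="\t", header=False, index=False
    )
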