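"""Per-site genotype tracks, depth filtering and binned heterozygosity.

A single diploid genome is summarised as a :class:`GenotypeTrack` (one row
per called site) and reduced to a :class:`HetBinTrack` — fixed-width bins
coded heterozygous / homozygous / missing — which is the observation
sequence consumed by the coalescent HMM.  Genome-wide heterozygosity H is
the proportion of heterozygous genotypes per genome base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

# bin state codes
BIN_HOM = 0
BIN_HET = 1
BIN_MISSING = 2

_BIN_CHAR = {BIN_HOM: "T", BIN_HET: "K", BIN_MISSING: "N"}
_CHAR_BIN = {v: k for k, v in _BIN_CHAR.items()}


@dataclass
class GenotypeTrack:
    """Per-site diploid genotype calls with depth and quality annotations.

    ``sites`` columns: scaffold, pos (1-based), genotype, depth, baseq, mapq.
    Positions must be strictly increasing within a scaffold.
    """

    sites: pd.DataFrame
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"scaffold", "pos", "genotype", "depth"}
        missing_cols = required - set(self.sites.columns)
        if missing_cols:
            raise ValueError(f"genotype table missing columns: {sorted(missing_cols)}")
        if "baseq" not in self.sites.columns:
            self.sites = self.sites.assign(baseq=60)
        if "mapq" not in self.sites.columns:
            self.sites = self.sites.assign(mapq=60)
        if (self.sites["depth"] < 0).any():
            raise ValueError("negative depth")
        for scaf, grp in self.sites.groupby("scaffold", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")
        for scaf in self.sites["scaffold"].unique():
            self.scaffold_lengths.setdefault(
                str(scaf), int(self.sites.loc[self.sites["scaffold"] == scaf, "pos"].max())
            )

    @property
    def genome_size_bp(self) -> int:
        return int(sum(self.scaffold_lengths.values()))


@dataclass
class HetBinTrack:
    """Genome partitioned into fixed-width bins coded HOM/HET/MISSING."""

    bins: dict[str, np.ndarray]  # int8 arrays per scaffold
    bin_size: int = 100
    genome_size_bp: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bins = {k: np.asarray(v, dtype=np.int8) for k, v in self.bins.items()}
        if self.genome_size_bp == 0:
            self.genome_size_bp = self.bin_size * self.n_bins

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.bins.values()))

    def het_fraction(self) -> float:
        """Fraction of non-missing bins that are heterozygous."""
        tot = het = 0
        for arr in self.bins.values():
            tot += int(np.sum(arr != BIN_MISSING))
            het += int(np.sum(arr == BIN_HET))
        return het / tot if tot else float("nan")


@dataclass
class HeterozygosityResult:
    H: float
    n_het_sites: int
    genome_size_bp: int
    n_sites_passing_filters: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def mean_doc(track: GenotypeTrack) -> float:
    """Arithmetic mean depth of coverage over called sites."""
    if len(track.sites) == 0:
        raise ValueError("empty genotype track")
    return float(track.sites["depth"].mean())


def filter_by_doc(track: GenotypeTrack, doc: float) -> GenotypeTrack:
    """Mask sites with depth outside [doc/3, 2*doc] as missing.

    Sites *less than* one third or *more than* double the mean depth are
    removed (boundaries inclusive, i.e. kept).  Removed sites stay in the
    table with genotype MISSING so binning can count them.
    """
    if doc <= 0:
        raise ValueError("mean depth must be positive")
    sites = track.sites.copy()
    d = sites["depth"].to_numpy(dtype=float)
    bad = (d < doc / 3.0) | (d > 2.0 * doc)
    sites.loc[bad, "genotype"] = MISSING
    return GenotypeTrack(sites, dict(track.scaffold_lengths))


def heterozygosity(
    track: GenotypeTrack,
    min_base_quality: float = 20,
    min_mapping_quality: float = 30,
    denominator: str = "genome",
) -> HeterozygosityResult:
    """Genome-wide heterozygosity H.

    Counts het genotypes passing the base-quality and mapping-quality
    filters and divides by total genome size (``denominator="genome"``) or,
    alternatively, by the number of sites passing filters
    (``denominator="callable"``).
    """
    if track.genome_size_bp <= 0:
        raise ValueError("genome size is zero")
    s = track.sites
    passing = (
        (s["genotype"] != MISSING)
        & (s["baseq"] >= min_base_quality)
        & (s["mapq"] >= min_mapping_quality)
    )
    n_pass = int(passing.sum())
    n_het = int(((s["genotype"] == HET) & passing).sum())
    if denominator == "genome":
        denom = track.genome_size_bp
    elif denominator == "callable":
        denom = max(n_pass, 1)
    else:
        raise ValueError("denominator must be 'genome' or 'callable'")
    return HeterozygosityResult(
        H=n_het / denom,
        n_het_sites=n_het,
        genome_size_bp=track.genome_size_bp,
        n_sites_passing_filters=n_pass,
    )


def bin_to_psmcfa(
    track: GenotypeTrack, bin_size: int = 100, missing_threshold: float = 0.9
) -> HetBinTrack:
    """Reduce a genotype track to fixed-width het/hom/missing bins.

    A bin is HET when it contains at least one heterozygous call, MISSING
    when more than ``missing_threshold`` of its sites are uncalled, else HOM.
    Sites absent from the table count as missing.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: dict[str, np.ndarray] = {}
    for scaf, length in track.scaffold_lengths.items():
        n = int(np.ceil(length / bin_size))
        if n == 0:
            raise ValueError(f"scaffold {scaf} shorter than one bin")
        grp = track.sites[track.sites["scaffold"] == scaf]
        idx = (grp["pos"].to_numpy() - 1) // bin_size  # 1-based -> 0-based bins
        het_mask = grp["genotype"].to_numpy() == HET
        called_mask = grp["genotype"].to_numpy() != MISSING
        n_called = np.bincount(idx[called_mask], minlength=n)
        n_het = np.bincount(idx[het_mask], minlength=n)
        bin_len = np.full(n, bin_size)
        bin_len[-1] = length - (n - 1) * bin_size
        missing_frac = 1.0 - n_called / bin_len
        arr = np.full(n, BIN_HOM, dtype=np.int8)
        arr[missing_frac > missing_threshold] = BIN_MISSING
        arr[n_het > 0] = BIN_HET
        bins[scaf] = arr
    return HetBinTrack(bins=bins, bin_size=bin_size, genome_size_bp=track.genome_size_bp)


def write_psmcfa(track: HetBinTrack, path, width: int = 60) -> None:
    """Write a het-bin track as FASTA-like text, alphabet {T, K, N}."""
    with open(path, "w") as fh:
        for scaf, arr in track.bins.items():
            fh.write(f">{scaf}\n")
            chars = "".join(_BIN_CHAR[int(v)] for v in arr)
            for i in range(0, len(chars), width):
                fh.write(chars[i : i + width] + "\n")


def read_psmcfa(path, bin_size: int = 100) -> HetBinTrack:
    bins: dict[str, list[int]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                bins[name] = []
            else:
                if name is None:
                    raise ValueError("sequence data before header")
                bins[name].extend(_CHAR_BIN[c] for c in line)
    return HetBinTrack(
        bins={k: np.array(v, dtype=np.int8) for k, v in bins.items()}, bin_size=bin_size
    )


def read_genotype_tsv(path) -> GenotypeTrack:
    """Read the simple TSV genotype dialect.

    Columns: scaffold, pos, genotype (hom-ref/het/hom-alt/missing or
    0/1/2/-1), depth, and optional baseq, mapq.  Scaffold lengths may be
    declared in ``#length scaffold value`` header lines.
    """
    lengths: dict[str, int] = {}
    with open(path) as fh:
        header_rows = 0
        for line in fh:
            if line.startswith("#length"):
                _, scaf, val = line.split()
                lengths[scaf] = int(val)
                header_rows += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=header_rows)
    name_map = {"hom-ref": HOM_REF, "het": HET, "hom-alt": HOM_ALT, "missing": MISSING}
    if df["genotype"].dtype == object:
        df["genotype"] = df["genotype"].map(name_map)
    return GenotypeTrack(df, lengths)


def write_genotype_tsv(track: GenotypeTrack, path) -> None:
    with open(path, "w") as fh:
        for scaf, length in track.scaffold_lengths.items():
            fh.write(f"#length {scaf} {length}\n")
        track.sites.to_csv(fh, sep="\t", index=False)


def read_vcf_genotypes(path, sample: int = 0) -> GenotypeTrack:
    """Load diploid genotypes plus DP from a VCF into a GenotypeTrack.

    Uses cyvcf2 when available; falls back to a minimal text parser for
    uncompressed VCFs (the deliverable keeps fixtures as plain text).
    """
    recs = []
    lengths: dict[str, int] = {}
    try:  # pragma: no cover - depends on optional library
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        for ctg, ln in zip(vcf.seqnames, vcf.seqlens or []):
            lengths[ctg] = int(ln)
        for v in vcf:
            gt = v.genotypes[sample]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                code = MISSING
            elif a == b == 0:
                code = HOM_REF
            elif a == b:
                code = HOM_ALT
            else:
                code = HET
            try:
                dp = int(v.format("DP")[sample][0])
            except (TypeError, KeyError):
                dp = int(v.INFO.get("DP", 0))
            recs.append((v.CHROM, v.POS, code, dp, v.QUAL or 60, 60))
    except ImportError:
        with open(path) as fh:
            samples: list[str] = []
            for line in fh:
                if line.startswith("##contig"):
                    inner = line.split("<", 1)[1].rstrip(">\n")
                    fields = dict(kv.split("=", 1) for kv in inner.split(","))
                    lengths[fields["ID"]] = int(fields.get("length", 0))
                    continue
                if line.startswith("#CHROM"):
                    samples = line.rstrip().split("\t")[9:]
                    continue
                if line.startswith("#"):
                    continue
                parts = line.rstrip().split("\t")
                fmt = parts[8].split(":")
                vals = dict(zip(fmt, parts[9 + sample].split(":")))
                gts = vals.get("GT", "./.").replace("|", "/").split("/")
                if "." in gts:
                    code = MISSING
                elif gts[0] == gts[1] == "0":
                    code = HOM_REF
                elif gts[0] == gts[1]:
                    code = HOM_ALT
                else:
                    code = HET
                dp = int(vals.get("DP", 0))
                recs.append((parts[0], int(parts[1]), code, dp, float(parts[5] or 60), 60))
    df = pd.DataFrame(recs, columns=["scaffold", "pos", "genotype", "depth", "baseq", "mapq"])
    return GenotypeTrack(df, lengths)
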