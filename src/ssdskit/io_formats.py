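"""Readers and writers for every on-disk artifact.

All fragment and hotspot intervals are BED6 (0-based half-open); SNP
tables are either VCF (1-based POS, converted on read) or a 4-column TSV
dialect with 0-based positions; aggregate profiles and footprints are
long-format TSV so runs can be diffed.  Writers emit stable, fully
deterministic text: rerunning a pipeline with the same seed must produce
byte-identical files.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam

from .types import GenomeModel, Hotspot, Snp, SsdnaFragment


class FormatError(ValueError):
    """Raised on malformed input files; message carries the line number."""


# ---------------------------------------------------------------------------
# fragments (BED6)
# ---------------------------------------------------------------------------

_TAG_NONE = "."


def _encode_fragment_name(frag: SsdnaFragment) -> str:
    tags = []
    if frag.truth_haplotype is not None:
        tags.append(f"hap={frag.truth_haplotype}")
    if frag.truth_role is not None:
        tags.append(f"role={frag.truth_role}")
    if frag.truth_hotspot is not None:
        tags.append(f"hs={frag.truth_hotspot}")
    if frag.truth_break is not None:
        tags.append(f"break={frag.truth_break}")
    return ";".join(tags) if tags else _TAG_NONE


def _decode_fragment_name(name: str) -> dict:
    out: dict = {}
    if name in (_TAG_NONE, ""):
        return out
    for item in name.split(";"):
        if "=" not in item:
            continue
        key, val = item.split("=", 1)
        if key == "hap":
            out["truth_haplotype"] = val
        elif key == "role":
            out["truth_role"] = val
        elif key == "hs":
            out["truth_hotspot"] = val
        elif key == "break":
            out["truth_break"] = int(val)
    return out


def write_fragments_bed(fragments: Iterable[SsdnaFragment], path: str) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(
                f"{frag.chrom}\t{frag.start}\t{frag.end}\t"
                f"{_encode_fragment_name(frag)}\t0\t{frag.strand}\n"
            )


def read_fragments_bed(path: str) -> list[SsdnaFragment]:
    """Read strand-specific ssDNA fragments from BED6.

    The strand column is mandatory ('+' or '-'): SSDS signal is
    meaningless without strand.  The name column optionally carries
    simulation truth tags (``hap=;role=;hs=;break=``).
    """
    fragments: list[SsdnaFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected BED6 (6 columns), got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: strand {strand!r} must be '+' or '-' "
                    "(strand is required for SSDS fragments)"
                )
            fragments.append(
                SsdnaFragment(chrom, start, end, strand, **_decode_fragment_name(name))
            )
    return fragments


# ---------------------------------------------------------------------------
# hotspots (BED6; metadata packed into the name field)
# ---------------------------------------------------------------------------


def write_hotspots_bed(hotspots: Iterable[Hotspot], path: str) -> None:
    """BED6 with ``center=<int>`` plus heat/f/class/x flags in the name."""
    with open(path, "w") as fh:
        for hs in hotspots:
            name = (
                f"{hs.hotspot_id};center={hs.center};heat={hs.heat:.10g};"
                f"f={hs.f_true:.10g};class={hs.prdm9_class};xnp={int(hs.on_x_nonpar)}"
            )
            fh.write(
                f"{hs.chrom}\t{hs.start}\t{hs.end}\t{name}\t0\t{hs.orientation}\n"
            )


def read_hotspots_bed(path: str) -> list[Hotspot]:
    hotspots: list[Hotspot] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            parts = name.split(";")
            hs_id = parts[0]
            meta = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
            if "center" not in meta:
                raise FormatError(f"{path}:{lineno}: hotspot name lacks center= tag")
            try:
                hotspots.append(
                    Hotspot(
                        chrom=chrom,
                        start=start,
                        end=end,
                        center=int(meta["center"]),
                        heat=float(meta.get("heat", 1.0)),
                        f_true=float(meta.get("f", 0.5)),
                        orientation=strand,
                        prdm9_class=meta.get("class", "CAST"),
                        on_x_nonpar=bool(int(meta.get("xnp", 0))),
                        hotspot_id=hs_id,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hotspots


# ---------------------------------------------------------------------------
# SNPs (VCF or TSV)
# ---------------------------------------------------------------------------


def write_snps_tsv(snps: Iterable[Snp], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tb6\tcast\n")
        for snp in snps:
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.allele_b6}\t{snp.allele_cast}\n")


def _read_snps_vcf(path: str) -> list[Snp]:
    """Biallelic SNPs from VCF.  REF is the B6 (reference) allele, ALT the
    CAST allele.  VCF POS is 1-based; pysam's ``start`` is already 0-based.
    Indels and multiallelic records are skipped with a summary warning."""
    snps: list[Snp] = []
    skipped = 0
    seen: set[tuple[str, int]] = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            key = (rec.chrom, rec.start)
            if key in seen:
                raise FormatError(
                    f"{path}: duplicate SNP position {rec.chrom}:{rec.pos} (1-based)"
                )
            seen.add(key)
            snps.append(Snp(rec.chrom, rec.start, rec.ref, alts[0]))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} non-SNP (indel/multiallelic) records")
    return snps


def _read_snps_tsv(path: str) -> list[Snp]:
    snps: list[Snp] = []
    seen: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["chrom", "pos"]:
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns (chrom pos b6 cast)")
            chrom, pos_s, b6, cast = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            if (chrom, pos) in seen:
                raise FormatError(f"{path}:{lineno}: duplicate SNP position {chrom}:{pos}")
            seen.add((chrom, pos))
            try:
                snps.append(Snp(chrom, pos, b6, cast))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return snps


def read_snps(path: str) -> list[Snp]:
    """Read a SNP table; dialect (VCF vs TSV) auto-detected from the header."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_snps_vcf(path)
    return _read_snps_tsv(path)


# ---------------------------------------------------------------------------
# genome (chrom sizes + x_nonpar)
# ---------------------------------------------------------------------------


def write_genome_tsv(genome: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        if genome.x_nonpar is not None:
            chrom, start, end = genome.x_nonpar
            fh.write(f"#x_nonpar\t{chrom}\t{start}\t{end}\n")
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_genome_tsv(path: str, snps: Optional[list[Snp]] = None) -> GenomeModel:
    chrom_sizes: dict[str, int] = {}
    x_nonpar = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#x_nonpar"):
                _, chrom, start, end = line.split("\t")
                x_nonpar = (chrom, int(start), int(end))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            chrom_sizes[fields[0]] = int(fields[1])
    return GenomeModel(chrom_sizes=chrom_sizes, snps=snps or [], x_nonpar=x_nonpar)


# ---------------------------------------------------------------------------
# profiles and footprints (long-format TSV)
# ---------------------------------------------------------------------------


def write_profile_tsv(profile, path: str) -> None:
    """Serialize a StrandProfile as long-format TSV (diff-friendly)."""
    with open(path, "w") as fh:
        fh.write(f"#binsize={profile.binsize}\n")
        fh.write(f"#half_width={profile.half_width}\n")
        fh.write(f"#n_hotspots={profile.n_hotspots}\n")
        fh.write("strand\trole\tbin_start\tvalue\n")
        for (strand, role), values in sorted(profile.values.items()):
            for bin_start, value in zip(profile.bin_starts, values):
                fh.write(f"{strand}\t{role}\t{bin_start}\t{float(value)!r}\n")


def read_profile_tsv(path: str):
    from .profiles import StrandProfile  # deferred to avoid import cycle

    meta: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].split("=", 1)
                meta[key] = int(val)
                continue
            if line.startswith("strand\t") or not line:
                continue
            strand, role, bin_start, value = line.split("\t")
            rows.append((strand, role, int(bin_start), float(value)))
    binsize, half_width = meta["binsize"], meta["half_width"]
    n_bins = 2 * half_width // binsize
    values: dict[tuple[str, str], np.ndarray] = {}
    for strand, role, bin_start, value in rows:
        key = (strand, role)
        if key not in values:
            values[key] = np.zeros(n_bins)
        idx = (bin_start + half_width) // binsize
        values[key][idx] = value
    return StrandProfile(
        binsize=binsize,
        half_width=half_width,
        n_hotspots=meta["n_hotspots"],
        values=values,
    )


def write_footprint_tsv(results, path: str) -> None:
    """Serialize deconvolution results (per-panel footprints + residuals)."""
    with open(path, "w") as fh:
        fh.write(f"#binsize={results.binsize}\n")
        fh.write(f"#half_width={results.half_width}\n")
        fh.write(f"#ridge={float(results.ridge)!r}\n")
        for (strand, role), res in sorted(results.residuals.items()):
            fh.write(f"#residual\t{strand}\t{role}\t{float(res)!r}\n")
        fh.write("strand\trole\tbin_start\tvalue\n")
        for (strand, role), values in sorted(results.footprints.items()):
            for bin_start, value in zip(results.bin_starts, values):
                fh.write(f"{strand}\t{role}\t{bin_start}\t{float(value)!r}\n")


def read_footprint_tsv(path: str) -> pd.DataFrame:
    """Footprint TSV as a tidy DataFrame (strand, role, bin_start, value)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_signal_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signal_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
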