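"""Readers and writers for the formats the pipeline touches.

Conventions, in one place:

* Genomic coordinates are 0-based half-open internally.  VCF is 1-based;
  the conversion happens here and only here.
* Variant panels travel as VCF 4.x with the per-site VAF in an INFO key
  (default ``AF``) and the biopsy purity in a ``##tumor_purity=`` header
  meta-line.  Only SNV records are used; others are skipped and counted.
* Consensus reads travel as FASTQ (Phred+33) with coordinates, repeat
  count and timestamp carried in the description as ``key=value`` pairs.
* Tables (length profiles, signatures, allele observations) are TSV with
  a header line, UTF-8, '.' decimal; scalar metadata rides in leading
  ``# key=value`` comment lines.
* Timestamps are minutes from run start, as floats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ConsensusRead
from .fragments import LengthProfile, SignatureMatrix
from .synth import AlleleObservations, VariantPanel, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "read_variant_panel_vcf",
    "write_variant_panel_vcf",
    "read_reads_fastq",
    "write_reads_fastq",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_signatures_tsv",
    "write_signatures_tsv",
    "read_observations_tsv",
    "write_observations_tsv",
    "RunConfig",
    "write_run_log",
]


# ---------------------------------------------------------------------------
# VCF variant panels
# ---------------------------------------------------------------------------


def write_variant_panel_vcf(panel: VariantPanel, path: str | Path, af_key: str = "AF") -> None:
    """Write a panel as an uncompressed VCF 4.2 file (1-based positions)."""
    header = pysam.VariantHeader()
    header.add_meta("tumor_purity", value=f"{panel.purity:.6g}")
    header.info.add(af_key, number="A", type="Float", description="Variant allele frequency in the tumor biopsy")
    for chrom in dict.fromkeys(s.chrom for s in panel.sites):
        max_pos = max(s.pos for s in panel.sites if s.chrom == chrom)
        header.contigs.add(chrom, length=max_pos + 2)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for s in panel.sites:
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos, stop=s.pos + 1, alleles=(s.ref, s.alt)
            )
            rec.info[af_key] = (float(s.vaf),)
            vcf.write(rec)


def read_variant_panel_vcf(
    path: str | Path, af_key: str = "AF", purity: float | None = None
) -> VariantPanel:
    """Read a tumor-informed SNV panel from VCF.

    VAF comes from INFO ``af_key``; purity from the ``##tumor_purity=``
    header meta-line unless overridden.  Non-SNV records are skipped with
    a logged count.
    """
    sites: list[VariantSite] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        if purity is None:
            for rec in vcf.header.records:
                if rec.key == "tumor_purity":
                    purity = float(rec.value)
                    break
        if purity is None:
            raise ValueError("no ##tumor_purity header meta-line; pass purity explicitly")
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or len(alts) != 1 or len(alts[0]) != 1:
                n_skipped += 1
                continue
            if af_key not in rec.info:
                raise ValueError(f"record {rec.chrom}:{rec.pos} lacks INFO key '{af_key}'")
            af = rec.info[af_key]
            if isinstance(af, tuple):
                af = af[0]
            sites.append(
                VariantSite(chrom=rec.chrom, pos=rec.start, ref=rec.ref, alt=alts[0], vaf=float(af))
            )
    if n_skipped:
        logger.info("skipped %d non-SNV records in %s", n_skipped, path)
    return VariantPanel(sites=tuple(sites), purity=purity)


# ---------------------------------------------------------------------------
# FASTQ consensus reads
# ---------------------------------------------------------------------------


def write_reads_fastq(reads: Sequence[ConsensusRead], path: str | Path) -> None:
    """Write consensus reads as FASTQ (Phred+33) with metadata in the header."""
    records = []
    for r in reads:
        chrom, start, end = r.coords
        rec = SeqRecord(
            Seq(r.seq),
            id=r.template_id,
            description=f"chrom={chrom} start={start} end={end} repeats={r.n_repeats} time={r.timestamp!r}",
        )
        rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads_fastq(path: str | Path) -> list[ConsensusRead]:
    """Read consensus reads written by :func:`write_reads_fastq`."""
    reads: list[ConsensusRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        try:
            coords = (fields["chrom"], int(fields["start"]), int(fields["end"]))
            n_repeats = int(fields["repeats"])
            timestamp = float(fields["time"])
        except KeyError as exc:
            raise ValueError(f"FASTQ record {rec.id} lacks metadata field {exc}") from exc
        reads.append(
            ConsensusRead(
                template_id=rec.id,
                seq=str(rec.seq),
                qual=tuple(rec.letter_annotations["phred_quality"]),
                n_repeats=n_repeats,
                coords=coords,
                timestamp=timestamp,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_meta_and_table(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        lineno = 0
        while line.startswith("#"):
            lineno += 1
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed metadata line {line!r}")
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    return meta, table


def write_profile_tsv(profile: LengthProfile, path: str | Path) -> None:
    pd.DataFrame({"length": profile.lengths, "density": profile.density}).to_csv(
        path, sep="\t", index=False
    )


def read_profile_tsv(path: str | Path) -> LengthProfile:
    _, df = _read_meta_and_table(path)
    if list(df.columns) != ["length", "density"]:
        raise ValueError(f"{path}: expected columns length, density; got {list(df.columns)}")
    lengths = df["length"].to_numpy(dtype=np.int64)
    if np.any(np.diff(lengths) != 1):
        raise ValueError(f"{path}: lengths must be consecutive integers")
    return LengthProfile(lo=int(lengths[0]), hi=int(lengths[-1]), density=df["density"].to_numpy())


def write_signatures_tsv(signatures: SignatureMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label={signatures.label}\n")
        pd.DataFrame(
            {
                "length": signatures.lengths,
                "signature1": signatures.sig1,
                "signature2": signatures.sig2,
            }
        ).to_csv(fh, sep="\t", index=False)


def read_signatures_tsv(path: str | Path) -> SignatureMatrix:
    meta, df = _read_meta_and_table(path)
    expected = ["length", "signature1", "signature2"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}; got {list(df.columns)}")
    lengths = df["length"].to_numpy(dtype=np.int64)
    return SignatureMatrix(
        lo=int(lengths[0]),
        hi=int(lengths[-1]),
        sig1=df["signature1"].to_numpy(),
        sig2=df["signature2"].to_numpy(),
        label=meta.get("label", "unknown"),
    )


def write_observations_tsv(obs: AlleleObservations, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_sites={obs.n_sites}\n")
        pd.DataFrame(
            {"site_index": obs.site_index, "call": obs.call, "timestamp": obs.timestamp}
        ).to_csv(fh, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> AlleleObservations:
    meta, df = _read_meta_and_table(path)
    if "n_sites" not in meta:
        raise ValueError(f"{path}: missing '# n_sites=' metadata line")
    expected = ["site_index", "call", "timestamp"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}; got {list(df.columns)}")
    return AlleleObservations(
        site_index=df["site_index"].to_numpy(dtype=np.int64),
        call=df["call"].to_numpy(dtype="U3") if len(df) else np.array([], dtype="U3"),
        timestamp=df["timestamp"].to_numpy(dtype=float),
        n_sites=int(meta["n_sites"]),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Seed plus free-form parameters for one pipeline run.

    Round-trips losslessly through YAML; ``config_hash`` gives a stable
    fingerprint for run logs.
    """

    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(seed=int(data["seed"]), params=data.get("params", {}))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def write_run_log(path: str | Path, config: RunConfig, **results: Any) -> None:
    """Write a structured JSON run log including seed and config hash."""
    payload = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "params": config.params,
        **results,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
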