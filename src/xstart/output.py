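"""Tabular output (TSV/BED/FASTA) and flat key-value config files.

Column names are frozen: downstream tooling may rely on them. Every table
carries a provenance comment line (tool version + config hash); genomic
spans in TSVs are 1-based inclusive, BED output is 0-based half-open with
the guide rank in the score column.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .guide_design import DesignConfig, GuideDesign
from .offtarget import OffTargetHit
from .variant_audit import AuditedVariant, AuditSummary

GUIDE_COLUMNS = [
    "gene_id",
    "spacer",
    "protospacer",
    "pam",
    "pam_class",
    "critical_position",
    "intended_edit",
    "bystanders",
    "rank",
]

HIT_COLUMNS = [
    "spacer_id",
    "contig",
    "start",
    "end",
    "strand",
    "match_length",
    "match_class",
    "gene_context",
]

VARIANT_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "transition_class",
    "context",
    "consequence",
    "attribution",
    "gene_id",
    "flank",
]


def config_hash(config: DesignConfig) -> str:
    text = repr(sorted(
        (k, sorted(v) if isinstance(v, frozenset) else v)
        for k, v in asdict(config).items()
    ))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _provenance(config: DesignConfig | None = None) -> str:
    line = f"# xstart v{__version__}"
    if config is not None:
        line += f" config={config_hash(config)}"
    return line + "\n"


def _span(guide: GuideDesign) -> str:
    iv = guide.protospacer
    return f"{iv.contig}:{iv.begin + 1}-{iv.end}:{iv.strand}"


def _edit_str(guide: GuideDesign) -> str:
    e = guide.intended_edit
    return f"{guide.protospacer.contig}:{e.genomic_pos + 1}:{e.ref_plus}>{e.alt_plus}"


def write_guides_tsv(
    guides: Sequence[GuideDesign], path: str | Path, config: DesignConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write("\t".join(GUIDE_COLUMNS) + "\n")
        for g in guides:
            by = ";".join(
                f"{b.spacer_position}:{b.context}:{b.consequence}" for b in g.bystanders
            )
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.spacer,
                        _span(g),
                        g.pam,
                        g.pam_class,
                        str(g.critical_position),
                        _edit_str(g),
                        by or ".",
                        str(g.rank),
                    ]
                )
                + "\n"
            )


def write_guides_bed(guides: Sequence[GuideDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in guides:
            iv = g.protospacer
            fh.write(
                f"{iv.contig}\t{iv.begin}\t{iv.end}\t{g.gene_id}.r{g.rank}\t"
                f"{g.rank}\t{iv.strand}\n"
            )


def write_spacers_fasta(guides: Sequence[GuideDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in guides:
            fh.write(f">{g.gene_id}.r{g.rank} {_span(g)}\n{g.spacer}\n")


def write_hits_tsv(
    hits: Sequence[OffTargetHit], path: str | Path, config: DesignConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            iv = h.interval
            fh.write(
                f"{h.spacer_id}\t{iv.contig}\t{iv.begin + 1}\t{iv.end}\t{iv.strand}\t"
                f"{h.match_length}\t{h.match_class}\t{h.gene_id}\n"
            )


def write_variants_tsv(variants: Sequence[AuditedVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance())
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.transition_class}\t"
                f"{v.context}\t{v.consequence}\t{v.attribution}\t"
                f"{v.gene_id or '.'}\t{v.flank}\n"
            )


def write_summary_tsv(summary: AuditSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance())
        fh.write("metric\tvalue\n")
        fh.write(f"total_offtarget\t{summary.total}\n")
        fh.write(f"total_including_intended\t{summary.total_including_intended}\n")
        for k in sorted(summary.by_transition):
            fh.write(f"transition.{k}\t{summary.by_transition[k]}\n")
        for k in sorted(summary.by_consequence):
            fh.write(f"consequence.{k}\t{summary.by_consequence[k]}\n")
        for k in sorted(summary.by_attribution):
            fh.write(f"attribution.{k}\t{summary.by_attribution[k]}\n")
        fh.write(
            f"fraction_noncoding_or_silent\t{summary.fraction_noncoding_or_silent:.4f}\n"
        )


def read_config_file(path: str | Path) -> dict:
    """Flat key=value file mirroring DesignConfig field names.

    ``window`` is a comma-separated list of spacer positions; ``start_set``
    a comma-separated codon list; booleans accept true/false/1/0.
    """
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad config line {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value
    out: dict = {}
    for key, value in raw.items():
        if key == "window":
            out[key] = frozenset(int(x) for x in value.split(","))
        elif key == "start_set":
            out[key] = frozenset(x.strip().upper() for x in value.split(","))
        elif key in ("spacer_length", "preferred_position", "seed_match_k", "table_id"):
            out[key] = int(value)
        elif key == "first_half_rule":
            out[key] = value.lower() in ("1", "true", "yes")
        elif key == "pam_mode":
            out[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return out


def read_bed(path: str | Path) -> list:
    """Minimal BED3+ reader used for scan masks."""
    from .genome_io import Interval

    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        strand = parts[5] if len(parts) > 5 else "+"
        out.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out
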