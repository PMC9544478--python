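"""Catalogue of novel ONSEN insertions and the genetics of their validation.

The package ships the published table of ten transposon insertion
polymorphisms (TIPs) detected in the drought-tolerant high-copy line 31
(hcLine31): chromosome, coordinate span, genomic context, disrupted gene
and zygosity.  Coordinate spans are printed in abbreviated form
("149387–91" means 149387..149391, the end sharing the start's leading
digits); zygosity is "(−/−)" for homozygous insertions and "(+/−)" for
heterozygous ones.

Candidate causal insertions are those that are both exonic and
homozygous: the uniform tolerance of all replicates of the line implies a
homozygous mutation, and a loss-of-function mechanism implies an exonic
hit.  Applied to the shipped table this leaves exactly the insertions in
AT1G58602, AT2G01290 (RPI2) and AT5G03435.

The module also encodes two bits of validation genetics: calling
insertion zygosity from a two-primer PCR band pattern (a ~5 kb insertion
suppresses the flanking-primer product), and the expected fraction of
drought-surviving F2 offspring under a recessive loss-of-function model
for the crosses that were used to confirm causality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "InsertionRecord",
    "BandPattern",
    "CONTEXTS",
    "load_table1",
    "read_insertion_table",
    "write_insertion_table",
    "filter_candidates",
    "call_zygosity_from_bands",
    "expected_f2_survival",
    "to_bed",
]

CONTEXTS = frozenset({"Exon", "Intron", "Promoter", "TE"})
HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"
ZYGOSITIES = frozenset({HOMOZYGOUS, HETEROZYGOUS})

# dash variants that appear in typeset coordinate spans and zygosity codes
_DASHES = "–—−‐-"
_SPAN_RE = re.compile(rf"^(\d+)[{_DASHES}](\d+)$")

_ZYGOSITY_CODES = {HOMOZYGOUS: "(−/−)", HETEROZYGOUS: "(+/−)"}
_MAX_SPAN = 10  # bp; insertion spans are target-site-duplication scale


@dataclass(frozen=True)
class InsertionRecord:
    """One TIP: a novel ONSEN insertion relative to the reference genome."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    context: str
    gene_id: str
    description: str
    zygosity: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.end - self.start + 1 > _MAX_SPAN:
            raise ValueError(
                f"span {self.start}-{self.end} exceeds {_MAX_SPAN} bp; "
                "not a target-site-scale insertion span"
            )
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class BandPattern:
    """Presence/absence of the two diagnostic PCR products for one plant:
    the flanking-primer (wild-type) band and the insertion-specific band."""

    wt_band_present: bool
    insertion_band_present: bool


def parse_span(span: str) -> tuple[int, int]:
    """Expand an abbreviated coordinate span.

    The printed end keeps only the digits that differ from the start:
    "149387–91" -> (149387, 149391).  A fully written end is also accepted.
    """
    m = _SPAN_RE.match(span.strip())
    if not m:
        raise ValueError(f"malformed coordinate span {span!r}")
    start_s, end_s = m.groups()
    start = int(start_s)
    if len(end_s) < len(start_s):
        end = int(start_s[: len(start_s) - len(end_s)] + end_s)
    else:
        end = int(end_s)
    return start, end


def format_span(start: int, end: int) -> str:
    """Render a span in the abbreviated table style: the end keeps its
    last digits (at least two, as printed) provided the remaining leading
    digits match the start."""
    s, e = str(start), str(end)
    if len(s) == len(e) and len(e) > 2:
        for suffix_len in range(2, len(e)):
            if e[: len(e) - suffix_len] == s[: len(s) - suffix_len]:
                e = e[len(e) - suffix_len :]
                break
    return f"{s}–{e}"


def _parse_zygosity(text: str) -> str:
    t = text.strip().strip("()")
    t = "".join("-" if c in _DASHES else c for c in t)
    if t == "-/-":
        return HOMOZYGOUS
    if t in ("+/-", "-/+"):
        return HETEROZYGOUS
    raise ValueError(f"unknown zygosity code {text!r}")


_COLUMNS = ["chr", "Coordinates", "Context", "ID", "Description", "Zygosity"]


def read_insertion_table(path: str | Path) -> list[InsertionRecord]:
    """Read a TIP table (TSV with the six published columns).

    Malformed rows are rejected with their line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after header
        try:
            start, end = parse_span(row["Coordinates"])
            records.append(
                InsertionRecord(
                    chromosome=str(row["chr"]).strip(),
                    start=start,
                    end=end,
                    context=str(row["Context"]).strip(),
                    gene_id=str(row["ID"]).strip(),
                    description=str(row["Description"]).strip(),
                    zygosity=_parse_zygosity(row["Zygosity"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
    return records


def write_insertion_table(records: list[InsertionRecord], path: str | Path) -> None:
    """Write records back to TSV in the published table style (abbreviated
    coordinate spans, symbolic zygosity)."""
    rows = [
        {
            "chr": r.chromosome,
            "Coordinates": format_span(r.start, r.end),
            "Context": r.context,
            "ID": r.gene_id,
            "Description": r.description,
            "Zygosity": _ZYGOSITY_CODES[r.zygosity],
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def load_table1() -> list[InsertionRecord]:
    """The packaged hcLine31 insertion table (10 TIPs)."""
    ref = resources.files("onsen_fate.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        return read_insertion_table(path)


def filter_candidates(
    records: list[InsertionRecord],
    contexts: frozenset[str] | set[str] | None = frozenset({"Exon"}),
    zygosity: str | None = HOMOZYGOUS,
) -> list[InsertionRecord]:
    """Order-preserving candidate filter.

    Defaults implement the causal-candidate rule (exonic and homozygous).
    Pass ``contexts=None`` / ``zygosity=None`` to disable either criterion.
    """
    out = []
    for r in records:
        if contexts is not None and r.context not in contexts:
            continue
        if zygosity is not None and r.zygosity != zygosity:
            continue
        out.append(r)
    return out


def call_zygosity_from_bands(pattern: BandPattern) -> str:
    """Genotype call from the two-band PCR assay.

    With elongation time limited, a homozygous ~5 kb insertion suppresses
    the flanking-primer (wild-type) product, so:
    wt band only -> wild-type homozygote; both bands -> heterozygote;
    insertion band only -> insertion homozygote; no band -> failed assay.
    """
    if pattern.wt_band_present and not pattern.insertion_band_present:
        return "wt_hom"
    if pattern.wt_band_present and pattern.insertion_band_present:
        return "heterozygous"
    if not pattern.wt_band_present and pattern.insertion_band_present:
        return "insertion_hom"
    return "failed"


_F2_SURVIVAL = {
    # F1 of hcLine31 x wild type is o/+ at RPI2; selfing gives 1:2:1 and
    # only o/o (no functional allele) survives the drought.
    "hc31_x_wt": 0.25,
    # hcLine31 x rpi2-1 combines two null alleles (ONSEN insertion, T-DNA)
    # at the same locus, so every F2 plant lacks a functional copy.
    "hc31_x_rpi2": 1.0,
    "wt_x_wt": 0.0,
}


def expected_f2_survival(cross: str) -> float:
    """Expected fraction of drought-surviving F2 plants under a recessive
    loss-of-function model at a single locus."""
    try:
        return _F2_SURVIVAL[cross]
    except KeyError:
        raise ValueError(
            f"unknown cross {cross!r}; expected one of {sorted(_F2_SURVIVAL)}"
        ) from None


def to_bed(records: list[InsertionRecord]) -> pd.DataFrame:
    """BED-style frame (0-based half-open) of the insertion spans."""
    return pd.DataFrame(
        {
            "chrom": [r.chromosome for r in records],
            "chromStart": [r.start - 1 for r in records],
            "chromEnd": [r.end for r in records],
            "name": [r.gene_id for r in records],
        }
    )
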