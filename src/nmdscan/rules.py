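"""The four NMD-escape rules, trigger-region delineation, and PTC calls.

The canonical rule space is the codon index (a PTC codon ``c`` is anchored
at reference CDS nucleotide ``3c - 2``).  Nucleotide bounds of the trigger
region derive from the start-proximal threshold ``T`` and the junction
window ``W`` as ``nt_lo = T + 1`` and ``nt_hi = J - W - 1`` (``J`` = last
junction); codon bounds are ``floor(nt / 3)`` of each.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .errors import PtcContractError
from .transcript import TranscriptModel, exon_of_cds_position, last_junction_position
from .variants import PtcCall

RULE_NAMES = ("last_exon", "junction_proximal", "long_exon", "start_proximal")

ESCAPE = "escape"
TRIGGER = "trigger"


class NmdRuleConfig(BaseModel):
    """Thresholds of the four surveillance rules.

    Defaults follow the usual formulation: PTCs under 150 nt from the start
    codon, within 50-55 nt upstream of the last junction (55 used here), in
    the last exon, or in exons over ~400 nt escape decay.
    """

    model_config = ConfigDict(frozen=True)

    start_proximal_nt: int = Field(default=150, gt=0)
    junction_window_nt: int = Field(default=55, ge=1)
    long_exon_nt: int = Field(default=400, gt=0)
    borderline_codons: int = Field(default=2, ge=0)


@dataclass(frozen=True)
class NmdRegion:
    """The codon/nt interval of a transcript where PTCs trigger decay."""

    nt_lo: Optional[int]
    nt_hi: Optional[int]
    codon_lo: Optional[int]
    codon_hi: Optional[int]
    excluded_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.codon_lo is None

    def trigger_codons(self) -> set[int]:
        """Explicit set of trigger codons (region minus exclusions)."""
        if self.is_empty:
            return set()
        codons = set(range(self.codon_lo, self.codon_hi + 1))
        for lo, hi in self.excluded_intervals:
            codons -= set(range(lo, hi + 1))
        return codons


@dataclass(frozen=True)
class NmdCall:
    """Escape/trigger verdict for one PTC."""

    status: str
    rules_fired: tuple[str, ...]
    borderline: bool
    ptc: PtcCall

    def __post_init__(self):
        if (self.status == ESCAPE) != bool(self.rules_fired):
            raise ValueError("escape status must coincide with fired rules")
        if self.borderline and self.status != TRIGGER:
            raise ValueError("borderline applies to trigger calls only")


_EMPTY = NmdRegion(None, None, None, None, [])


def _codon_lo_bound(cfg: NmdRuleConfig) -> int:
    return max(1, (cfg.start_proximal_nt + 1) // 3)


def _exon_codon_span(prev_junction: int, exon_end: int) -> tuple[int, int]:
    # codon c lies in the exon iff its anchor nt (3c - 2) does
    c_min = (prev_junction + 5) // 3
    c_max = (exon_end + 2) // 3
    return c_min, c_max


def trigger_region(t: TranscriptModel, cfg: NmdRuleConfig | None = None) -> NmdRegion:
    """Delineate the transcript's NMD-trigger region.

    Empty when the transcript has a single coding exon or the thresholds
    close the interval.  Codons of the region falling in an over-length
    exon (long-exon rule) are reported as excluded sub-intervals.
    """
    cfg = cfg or NmdRuleConfig()
    junction = last_junction_position(t)
    if junction is None:
        return _EMPTY
    nt_lo = cfg.start_proximal_nt + 1
    nt_hi = junction - cfg.junction_window_nt - 1
    if nt_lo > nt_hi:
        return _EMPTY
    codon_lo = max(1, nt_lo // 3)
    codon_hi = nt_hi // 3
    if codon_lo > codon_hi:
        return _EMPTY
    excluded: list[tuple[int, int]] = []
    boundaries = [0] + t.exon_junctions_cds
    for i, length in enumerate(t.exon_cds_lengths[:-1]):  # last exon exempt
        if length <= cfg.long_exon_nt:
            continue
        lo, hi = _exon_codon_span(boundaries[i], boundaries[i] + length)
        lo, hi = max(lo, codon_lo), min(hi, codon_hi)
        if lo <= hi:
            excluded.append((lo, hi))
    return NmdRegion(nt_lo, nt_hi, codon_lo, codon_hi, excluded)


def classify_ptc(
    t: TranscriptModel, ptc: PtcCall, cfg: NmdRuleConfig | None = None
) -> NmdCall:
    """Classify a PTC against the four rules.

    The PTC is anchored at reference codon space nucleotide
    ``3 * codon_index - 2`` (frameshift PTCs are placed by their resulting
    codon, not the mutation site).
    """
    cfg = cfg or NmdRuleConfig()
    c = ptc.codon_index
    if c >= t.n_codons:
        raise PtcContractError(
            f"codon {c} is at/after the natural terminator (codon {t.n_codons})"
        )
    anchor = 3 * c - 2
    junction = last_junction_position(t)
    fired: set[str] = set()
    if c < _codon_lo_bound(cfg):
        fired.add("start_proximal")
    if junction is None or anchor > junction:
        fired.add("last_exon")
    elif c > (junction - cfg.junction_window_nt - 1) // 3:
        fired.add("junction_proximal")
    exon_idx, exon_len = exon_of_cds_position(t, anchor)
    if exon_idx < len(t.exon_cds_lengths) and exon_len > cfg.long_exon_nt:
        fired.add("long_exon")
    status = ESCAPE if fired else TRIGGER
    borderline = False
    if status == TRIGGER:
        region = trigger_region(t, cfg)
        b = cfg.borderline_codons
        borderline = (
            not region.is_empty
            and (c - region.codon_lo <= b or region.codon_hi - c <= b)
        )
    ordered = tuple(r for r in RULE_NAMES if r in fired)
    return NmdCall(status=status, rules_fired=ordered, borderline=borderline, ptc=ptc)
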