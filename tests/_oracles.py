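"""Brute-force re-derivations used to cross-check the rule engine."""
from __future__ import annotations

from nmdscan.rules import NmdRuleConfig


def trigger_codon_set(exon_lengths: list[int], cfg: NmdRuleConfig) -> set[int]:
    """Per-codon re-derivation of the trigger set from exon partial sums.

    A codon c (anchored at nt 3c - 2) triggers decay iff it is not
    start-proximal, not at/after the last junction, not within the
    junction window, and not inside an over-length non-terminal exon.
    """
    total = sum(exon_lengths)
    n_codons = total // 3
    junctions = []
    acc = 0
    for length in exon_lengths[:-1]:
        acc += length
        junctions.append(acc)
    if not junctions:
        return set()
    last_junction = junctions[-1]
    triggers: set[int] = set()
    for codon in range(1, n_codons):  # natural stop excluded
        anchor = 3 * codon - 2
        if codon < max(1, (cfg.start_proximal_nt + 1) // 3):
            continue  # start-proximal escape
        if anchor > last_junction:
            continue  # last-exon escape
        if codon > (last_junction - cfg.junction_window_nt - 1) // 3:
            continue  # junction-proximal escape
        acc = 0
        in_long_exon = False
        for i, length in enumerate(exon_lengths):
            if acc < anchor <= acc + length:
                in_long_exon = i < len(exon_lengths) - 1 and length > cfg.long_exon_nt
                break
            acc += length
        if in_long_exon:
            continue
        triggers.add(codon)
    return triggers
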