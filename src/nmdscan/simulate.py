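"""Synthetic transcripts, PTC-introducing variants with ground truth, and
binomial DNA/RNA read counts.

Ground-truth PTCs are derived through a minimal independent code path
(hand-written codon table, direct slicing) so the variant engine can be
tested against it.  All randomness flows from one root seed through fixed
per-component child streams.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .ase import AlleleCounts
from .errors import SimulationConfigError
from .transcript import TranscriptModel
from .variants import CdsVariant, PtcCall, format_hgvs, normalize_variant

# Standard genetic code, written out by hand (independent of Bio.Seq).
_BASES = "TCAG"
_AA64 = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa == "*")

VARIANT_CLASSES = ("nonsense", "frameshift_del", "frameshift_ins", "frameshift_dup", "delins")

# fixed offsets for per-component child RNG streams
_STREAM_TRANSCRIPT = 1
_STREAM_VARIANT = 2
_STREAM_COUNTS = 3


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_exons: tuple[int, int] = (2, 6)
    exon_len_nt: tuple[int, int] = (20, 400)
    cds_codons: tuple[int, int] = (80, 250)
    variant_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "nonsense": 0.2,
            "frameshift_del": 0.2,
            "frameshift_ins": 0.2,
            "frameshift_dup": 0.2,
            "delins": 0.2,
        }
    )
    depth_dna: int = Field(default=100, gt=0)
    depth_rna: int = Field(default=100, gt=0)
    retention_delta: float = Field(default=0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("n_exons", "exon_len_nt", "cds_codons"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise SimulationConfigError(f"empty range for {name}: {lo}..{hi}")
        if set(self.variant_mix) - set(VARIANT_CLASSES):
            raise SimulationConfigError(
                f"unknown variant classes {set(self.variant_mix) - set(VARIANT_CLASSES)}"
            )
        if abs(sum(self.variant_mix.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("variant_mix proportions must sum to 1")
        return self


def _child_rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def make_transcript(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TranscriptModel:
    """Draw a valid multi-exon transcript: ATG, sense codons, one stop."""
    rng = rng if rng is not None else _child_rng(cfg, _STREAM_TRANSCRIPT)
    n_codons = int(rng.integers(cfg.cds_codons[0], cfg.cds_codons[1] + 1))
    body = rng.choice(SENSE_CODONS, size=max(n_codons - 2, 0))
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    cds = "ATG" + "".join(body) + stop
    lengths = _partition_exons(cfg, len(cds), rng)
    return TranscriptModel(
        transcript_id=f"SYN{cfg.seed}_{n_codons}aa_{len(lengths)}ex",
        cds_sequence=cds,
        exon_cds_lengths=lengths,
    )


def _partition_exons(
    cfg: SimulationConfig, total: int, rng: np.random.Generator
) -> list[int]:
    lo, hi = cfg.exon_len_nt
    feasible = [
        n
        for n in range(cfg.n_exons[0], cfg.n_exons[1] + 1)
        if n * lo <= total <= n * hi
    ]
    if not feasible:
        raise SimulationConfigError(
            f"no exon count in {cfg.n_exons} can partition {total} nt "
            f"with per-exon lengths in {cfg.exon_len_nt}"
        )
    n = int(rng.choice(feasible))
    lengths = np.full(n, lo, dtype=int)
    remaining = total - n * lo
    cap = hi - lo
    while remaining > 0:
        open_exons = np.flatnonzero(lengths - lo < cap)
        take = min(remaining, len(open_exons))
        chosen = rng.choice(open_exons, size=take, replace=False)
        lengths[chosen] += 1
        remaining -= take
    return [int(x) for x in lengths]


# -- independent ground-truth path ----------------------------------------


def _oracle_apply(seq: str, v: CdsVariant) -> str:
    if v.kind == "substitution":
        return seq[: v.start - 1] + v.alt_allele + seq[v.start :]
    if v.kind == "deletion":
        return seq[: v.start - 1] + seq[v.end :]
    if v.kind == "duplication":
        return seq[: v.end] + seq[v.start - 1 : v.end] + seq[v.end :]
    if v.kind == "insertion":
        return seq[: v.start] + v.alt_allele + seq[v.start :]
    return seq[: v.start - 1] + v.alt_allele + seq[v.end :]


def expected_ptc(t: TranscriptModel, v: CdsVariant) -> Optional[PtcCall]:
    """Ground-truth PTC by direct codon-table translation of the edit.

    Independent of :func:`nmdscan.variants.find_ptc`: uses the hand-written
    codon table and locates the edit from the variant's own coordinates
    rather than by sequence comparison.  Returns None for the natural stop
    and for stop-less frames.
    """
    mutant = _oracle_apply(t.cds_sequence, v)
    # 1-based mutant position of the last nucleotide guaranteed unchanged
    # 5' of the edit, from the variant's own coordinates
    if v.kind == "insertion":
        unchanged_through = v.start
    elif v.kind == "duplication":
        unchanged_through = v.end
    else:  # substitution / deletion / delins modify from v.start onward
        unchanged_through = v.start - 1
    net = v.length_delta
    for i in range(1, len(mutant) // 3 + 1):
        codon = mutant[3 * i - 3 : 3 * i]
        if CODON_TABLE[codon] != "*":
            continue
        first_mut = 3 * i - 2
        shift = net if first_mut > unchanged_through else 0
        first_ref = first_mut - shift
        if shift % 3 == 0 and (first_ref + 2) // 3 == t.n_codons:
            return None
        return PtcCall(codon_index=i, cds_first_nt=first_ref, cds_last_nt=first_ref + 2)
    return None  # stop-loss


def implant_variant(
    t: TranscriptModel,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 50,
) -> tuple[CdsVariant, Optional[PtcCall]]:
    """Draw a PTC-introducing variant plus its ground-truth PTC.

    Resamples (bounded) when the draw yields a stop-less frame or no
    premature stop, so callers almost always receive a usable PTC strictly
    before the natural terminator.
    """
    rng = rng if rng is not None else _child_rng(cfg, _STREAM_VARIANT)
    kinds = sorted(cfg.variant_mix)
    probs = np.array([cfg.variant_mix[k] for k in kinds])
    last: tuple[CdsVariant, Optional[PtcCall]] | None = None
    for _ in range(max_tries):
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        v = _draw_variant(t, kind, rng)
        if v is None:
            continue
        truth = expected_ptc(t, v)
        last = (v, truth)
        if truth is not None and truth.codon_index < t.n_codons:
            return v, truth
    if last is None:
        raise SimulationConfigError("could not draw any variant")
    return last


def _draw_variant(
    t: TranscriptModel, kind: str, rng: np.random.Generator
) -> Optional[CdsVariant]:
    seq = t.cds_sequence
    L = len(seq)
    if kind == "nonsense":
        options = []
        for codon_i in range(2, t.n_codons):  # exclude ATG and natural stop
            codon = seq[3 * codon_i - 3 : 3 * codon_i]
            for offset, alt in itertools.product(range(3), "ACGT"):
                if alt == codon[offset]:
                    continue
                mutated = codon[:offset] + alt + codon[offset + 1 :]
                if CODON_TABLE[mutated] == "*":
                    options.append((3 * codon_i - 2 + offset, codon[offset], alt))
        if not options:
            return None
        pos, ref, alt = options[int(rng.integers(len(options)))]
        v = CdsVariant("substitution", pos, pos, ref, alt)
    elif kind == "frameshift_del":
        span = int(rng.integers(1, 3))
        start = int(rng.integers(4, L - 3 - span))
        v = CdsVariant("deletion", start, start + span - 1, seq[start - 1 : start + span - 1])
    elif kind == "frameshift_ins":
        span = int(rng.integers(1, 3))
        pos = int(rng.integers(3, L - 3))
        alt = "".join(rng.choice(list("ACGT"), size=span))
        v = CdsVariant("insertion", pos, pos + 1, "", alt)
    elif kind == "frameshift_dup":
        span = int(rng.integers(1, 3))
        start = int(rng.integers(4, L - 3 - span))
        v = CdsVariant("duplication", start, start + span - 1, seq[start - 1 : start + span - 1])
    else:  # delins, frameshifting by construction
        span = int(rng.integers(1, 4))
        start = int(rng.integers(4, L - 3 - span))
        alt_len = span + (1 if rng.integers(2) else 2)
        alt = "".join(rng.choice(list("ACGT"), size=alt_len))
        v = CdsVariant("delins", start, start + span - 1, seq[start - 1 : start + span - 1], alt)
    v = normalize_variant(v, seq)
    return CdsVariant(
        v.kind, v.start, v.end, v.ref_allele, v.alt_allele, raw_hgvs=format_hgvs(v)
    )


def simulate_counts(
    delta: float,
    depth_dna: int,
    depth_rna: int,
    seed: int | np.random.Generator = 0,
    sample_id: str = "",
) -> AlleleCounts:
    """Binomial read counts for a heterozygous PTC with retention ``delta``.

    DNA alt reads ~ Binomial(depth_dna, 0.5); the RNA alt probability is
    ``0.5 * delta / (0.5 * delta + 0.5)`` (mutant transcripts survive at
    rate delta relative to wild type).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng([int(seed), _STREAM_COUNTS])
    )
    dna_alt = int(rng.binomial(depth_dna, 0.5))
    p_rna = 0.5 * delta / (0.5 * delta + 0.5)
    rna_alt = int(rng.binomial(depth_rna, p_rna))
    return AlleleCounts(
        dna_alt=dna_alt,
        dna_ref=depth_dna - dna_alt,
        rna_alt=rna_alt,
        rna_ref=depth_rna - rna_alt,
        sample_id=sample_id,
    )
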