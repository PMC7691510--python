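"""Orchestration: variant table -> PTC calls -> NMD classification report."""
from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .errors import (
    HgvsParseError,
    NmdscanError,
    NotCodingEditError,
)
from .rules import ESCAPE, TRIGGER, NmdRuleConfig, classify_ptc, trigger_region
from .transcript import TranscriptModel
from .variants import (
    PtcCall,
    TranscriptEdit,
    apply_variant,
    find_ptc,
    parse_cdna_hgvs,
    protein_hgvs_of,
    ptc_codon_from_protein_hgvs,
)

VARIANT_TSV_COLUMNS = ("hgvs_c", "hgvs_p", "label", "edit_spec")


@dataclass
class ReportRow:
    label: str
    hgvs_c: str
    hgvs_p_printed: str
    variant_class: str
    resolution: str  # sequence | edit | protein | error
    ptc_codon: Optional[int]
    ptc_cds_nt: Optional[int]
    protein_hgvs_computed: str
    status: str  # escape | trigger | no_ptc | error
    rules_fired: tuple[str, ...]
    borderline: bool
    discordant: bool
    error: str


@dataclass
class ClassificationReport:
    transcript_id: str
    rows: list[ReportRow]
    summary: dict
    region: dict
    config: dict
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec = asdict(row)
            rec["rules_fired"] = ",".join(row.rules_fired)
            records.append(rec)
        return pd.DataFrame.from_records(
            records, columns=[f.name for f in ReportRow.__dataclass_fields__.values()]
        )

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    def to_json(self) -> str:
        payload = {
            "transcript_id": self.transcript_id,
            "region": self.region,
            "summary": self.summary,
            "config": self.config,
            "rows": [asdict(r) | {"rules_fired": list(r.rules_fired)} for r in self.rows],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def load_variant_table(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    if "hgvs_c" not in df.columns:
        raise NmdscanError("variant table must have an hgvs_c column")
    for col in VARIANT_TSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df.fillna("")


def region_description(t: TranscriptModel, cfg: NmdRuleConfig | None = None) -> dict:
    """Machine-readable trigger-region description (``run_region``)."""
    cfg = cfg or NmdRuleConfig()
    region = trigger_region(t, cfg)
    if region.is_empty:
        text = "trigger: none"
    else:
        text = (
            f"trigger: codons {region.codon_lo}-{region.codon_hi} "
            f"(nt {region.nt_lo}-{region.nt_hi})"
        )
        if region.excluded_intervals:
            excl = ", ".join(f"{lo}-{hi}" for lo, hi in region.excluded_intervals)
            text += f"; long-exon exclusions: codons {excl}"
    return {
        "transcript_id": t.transcript_id,
        "cds_length_nt": t.cds_length,
        "n_codons": t.n_codons,
        "last_junction_nt": (t.exon_junctions_cds or [None])[-1],
        "nt_lo": region.nt_lo,
        "nt_hi": region.nt_hi,
        "codon_lo": region.codon_lo,
        "codon_hi": region.codon_hi,
        "excluded_intervals": [list(x) for x in region.excluded_intervals],
        "description": text,
    }


run_region = region_description


def _variant_class(kind: str, length_delta: int, has_ptc: bool) -> str:
    if kind == "substitution":
        return "nonsense" if has_ptc else "substitution"
    if length_delta % 3 != 0:
        return "frameshift"
    return "inframe"


def _parse_edit_spec(spec: str) -> TranscriptEdit:
    payload = json.loads(spec)
    return TranscriptEdit(
        insert_position=int(payload["insert_position"]),
        inserted_sequence=str(payload["inserted_sequence"]),
    )


def run_classification(
    transcript: TranscriptModel,
    variants: Union[str, Path, pd.DataFrame],
    cfg: NmdRuleConfig | None = None,
    prefer_printed: bool = False,
) -> ClassificationReport:
    """Classify every variant row against the transcript's NMD rules.

    Resolution order per row: sequence application of the cDNA HGVS, then a
    supplied ``edit_spec`` (splice consequences), then the printed protein
    HGVS.  When both a computed and a printed protein name exist and
    disagree, the row is flagged discordant; the computed call wins unless
    ``prefer_printed``.
    """
    cfg = cfg or NmdRuleConfig()
    table = load_variant_table(variants)
    rows: list[ReportRow] = []
    for rec in table.itertuples(index=False):
        rows.append(_classify_row(transcript, rec, cfg, prefer_printed))
    summary = _summarize(rows)
    return ClassificationReport(
        transcript_id=transcript.transcript_id,
        rows=rows,
        summary=summary,
        region=region_description(transcript, cfg),
        config=cfg.model_dump(),
        metadata={"tool": "nmdscan", "version": __version__},
    )


def _classify_row(
    t: TranscriptModel, rec, cfg: NmdRuleConfig, prefer_printed: bool
) -> ReportRow:
    hgvs_c = getattr(rec, "hgvs_c", "") or ""
    hgvs_p = getattr(rec, "hgvs_p", "") or ""
    label = getattr(rec, "label", "") or hgvs_c
    edit_spec = getattr(rec, "edit_spec", "") or ""

    ptc: Optional[PtcCall] = None
    resolution = "error"
    variant_class = "unknown"
    computed_php = ""
    error = ""
    try:
        try:
            variant = parse_cdna_hgvs(hgvs_c)
            mutant = apply_variant(t, variant)
            ptc = find_ptc(t, mutant)
            resolution = "sequence"
            computed_php = ptc.protein_hgvs if ptc else ""
            variant_class = _variant_class(variant.kind, variant.length_delta, ptc is not None)
        except NotCodingEditError:
            variant_class = "splicing"
            if edit_spec:
                edit = _parse_edit_spec(edit_spec)
                mutant = apply_variant(t, edit)
                ptc = find_ptc(t, mutant)
                resolution = "edit"
                computed_php = ptc.protein_hgvs if ptc else ""
            elif hgvs_p:
                codon = ptc_codon_from_protein_hgvs(hgvs_p)
                ptc = PtcCall(
                    codon_index=codon,
                    cds_first_nt=3 * codon - 2,
                    cds_last_nt=3 * codon,
                    protein_hgvs=hgvs_p,
                )
                resolution = "protein"
            else:
                raise
    except (NmdscanError, ValueError, KeyError) as exc:
        return ReportRow(
            label=label, hgvs_c=hgvs_c, hgvs_p_printed=hgvs_p,
            variant_class=variant_class, resolution="error",
            ptc_codon=None, ptc_cds_nt=None, protein_hgvs_computed="",
            status="error", rules_fired=(), borderline=False,
            discordant=False, error=str(exc),
        )

    discordant = False
    if computed_php and hgvs_p:
        printed_codon = None
        try:
            printed_codon = ptc_codon_from_protein_hgvs(hgvs_p)
        except NmdscanError:
            pass
        discordant = hgvs_p.replace(" ", "") != computed_php and (
            printed_codon is None or ptc is None or printed_codon != ptc.codon_index
        )
        if prefer_printed and printed_codon is not None and ptc is not None:
            ptc = PtcCall(
                codon_index=printed_codon,
                cds_first_nt=3 * printed_codon - 2,
                cds_last_nt=3 * printed_codon,
                protein_hgvs=hgvs_p,
            )
            resolution = "protein"

    if ptc is None:
        return ReportRow(
            label=label, hgvs_c=hgvs_c, hgvs_p_printed=hgvs_p,
            variant_class=variant_class, resolution=resolution,
            ptc_codon=None, ptc_cds_nt=None, protein_hgvs_computed="",
            status="no_ptc", rules_fired=(), borderline=False,
            discordant=False, error="",
        )
    call = classify_ptc(t, ptc, cfg)
    return ReportRow(
        label=label, hgvs_c=hgvs_c, hgvs_p_printed=hgvs_p,
        variant_class=variant_class, resolution=resolution,
        ptc_codon=ptc.codon_index, ptc_cds_nt=ptc.cds_first_nt,
        protein_hgvs_computed=computed_php,
        status=call.status, rules_fired=call.rules_fired,
        borderline=call.borderline, discordant=discordant, error="",
    )


def _summarize(rows: list[ReportRow]) -> dict:
    by_class: dict[str, int] = {}
    by_rule: dict[str, int] = {}
    n_escape = n_trigger = n_borderline = n_no_ptc = n_error = 0
    for row in rows:
        by_class[row.variant_class] = by_class.get(row.variant_class, 0) + 1
        for rule in row.rules_fired:
            by_rule[rule] = by_rule.get(rule, 0) + 1
        if row.status == ESCAPE:
            n_escape += 1
        elif row.status == TRIGGER:
            n_trigger += 1
            n_borderline += int(row.borderline)
        elif row.status == "no_ptc":
            n_no_ptc += 1
        else:
            n_error += 1
    return {
        "total": len(rows),
        "by_class": dict(sorted(by_class.items())),
        "by_rule": dict(sorted(by_rule.items())),
        "n_escape": n_escape,
        "n_trigger": n_trigger,
        "n_borderline": n_borderline,
        "n_no_ptc": n_no_ptc,
        "n_error": n_error,
    }
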