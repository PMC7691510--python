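"""Bundled fixtures: the SOD1 transcript model and its curated PTC table."""
from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .pipeline import load_variant_table
from .transcript import TranscriptModel, load_transcript

_DATA = files("nmdscan.data")


def sod1_path() -> Path:
    return Path(str(_DATA / "sod1_nm000454.json"))


def table1_path() -> Path:
    return Path(str(_DATA / "sod1_ptc_variants.tsv"))


def sod1_transcript() -> TranscriptModel:
    """SOD1 transcript model (NM_000454.4 CDS, 154 codons + stop)."""
    return load_transcript(sod1_path(), format="json")


def sod1_variants() -> pd.DataFrame:
    """The 16 curated disease-associated PTC variants of SOD1."""
    return load_variant_table(table1_path())
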