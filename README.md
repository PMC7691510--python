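# nmdscan

Consequence calling for premature termination codons (PTCs) and prediction
of nonsense-mediated mRNA decay (NMD) escape, with allele-specific
expression evidence. Given a protein-coding transcript model and a table of
cDNA-level variants, `nmdscan`:

1. parses the HGVS `c.` description, applies it to the CDS, translates the
   mutant frame and locates the resulting PTC (with protein-level `p.`
   nomenclature);
2. classifies the PTC against the four NMD surveillance rules — last exon,
   junction-proximal (50–55 nt window), long exon (>~400 nt), and
   start-proximal (<150 nt from the start codon) — and delineates the
   transcript's NMD-trigger region, flagging borderline positions;
3. compares DNA vs RNA variant allele fractions for a heterozygous PTC and
   issues a decay/escape/indeterminate verdict from an exact binomial test
   and an odds-ratio estimate of mutant-transcript retention;
4. simulates transcripts, PTC-introducing variants with ground truth, and
   binomial read counts so every stage is testable offline.

A bundled fixture carries the human *SOD1* transcript (CDS of
NM_000454.4, 154 codons + stop, exon junctions at CDS nt 72/169/240/357)
and its 16 curated disease-associated PTC variants. With default
thresholds the *SOD1* trigger region is CDS nt 151–301 (codons 50–100);
15 of the 16 variants escape (14 by the last-exon rule, 1 start-proximal)
and the single trigger at codon 100 is flagged borderline.

## CLI

```sh
# trigger region of a transcript (JSON, GenBank, or GFF3+FASTA input)
nmdscan region --transcript src/nmdscan/data/sod1_nm000454.json

# classify a variant TSV (columns: hgvs_c, optional hgvs_p/label/edit_spec)
nmdscan classify --transcript src/nmdscan/data/sod1_nm000454.json \
    --variants src/nmdscan/data/sod1_ptc_variants.tsv --out report.json

# DNA-vs-RNA allelic imbalance verdicts
nmdscan ase --counts counts.tsv   # sample_id dna_alt dna_ref rna_alt rna_ref

# synthetic transcript + variants + truth + read counts
nmdscan simulate --seed 1 --n-variants 20 --outdir sim/
```

Rule thresholds are configurable via `--config` (JSON or `key=value`
lines): `start_proximal_nt`, `junction_window_nt`, `long_exon_nt`,
`borderline_codons`.

Splice-altering variants (intronic HGVS) are not predicted; supply their
transcript-level consequence as an inline `edit_spec` JSON
(`{"insert_position": ..., "inserted_sequence": ...}`) or a protein-level
`hgvs_p`, and the pipeline resolves rows in the order
sequence > edit > protein.

## Library use

```python
from nmdscan import (apply_variant, classify_ptc, find_ptc,
                     parse_cdna_hgvs, trigger_region)
from nmdscan.datasets import sod1_transcript

t = sod1_transcript()
ptc = find_ptc(t, apply_variant(t, parse_cdna_hgvs("c.380T>A")))
call = classify_ptc(t, ptc)      # escape, rules_fired=("last_exon",)
region = trigger_region(t)       # codons 50-100, nt 151-301
```

Limitations: single-isoform, CDS-coordinate model (UTRs ignored); no
splice-site prediction; the read-count model is binomial without mapping
bias or overdispersion; the retention odds-ratio assumes equal DNA
representation of both alleles.
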