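# fernmir

Conserved plant microRNA analysis for small-RNA sequencing libraries, built
around a fern (*Pleopeltis minima*) case study: read preprocessing, conserved
miRNA family identification, target-site prediction, TAS3 tasiRNA phasing, and
Dollo-parsimony origin mapping of miRNA families on the land-plant cladogram.

## The science

Plant microRNAs (miRNAs) are ~21-nt regulatory RNAs excised by DCL1 from
hairpin precursors as a miRNA/miRNA\* duplex with 2-nt 3' overhangs. Deeply
conserved families (miR156, miR159/319, miR166, miR390, ...) predate the major
land-plant radiations and can be recognised in a new species purely by sequence
similarity to curated mature miRNAs. This package implements that comparative
workflow end to end:

1. **Preprocessing** — adapter trimming, 15–40 nt length filtering, collapsing
   to unique tags, contaminant removal, reads-per-million (RPM) normalisation
   and the length histogram whose 21-nt (miRNA) and 24-nt (siRNA) peaks
   characterise a healthy plant sRNA library.
2. **Identification** — ungapped alignment of tags to mature reference miRNAs
   allowing ≤ 2 mismatches and ≤ 3 nt of end variation, grouping into canonical
   families (miR157→miR156, miR165→miR166, miR530/1030 merged; optional
   miR156/529 and miR159/319 superfamilies), and bona fide acceptance
   requiring ≥ 10 reads of 20–22 nt, consistent 5' processing (homogeneity
   ≥ 0.75), and close similarity to a high-confidence reference — with a
   rescue path when both duplex arms (5p and 3p) are observed. Similarity is
   summarised by an ungapped Karlin–Altschul E-value, and a stringent
   reassessment keeps candidates with E < 0.01 and ≥ 1 RPM.
3. **Targets** — position-weighted complementarity scoring (Watson–Crick 0,
   G:U 0.5, mismatch 1, gap 2; penalties doubled at miRNA positions 2–13),
   reporting sites with expectation E ≤ 3.0 (relaxed to 4.0 for miR168), with
   5'UTR/CDS/3'UTR region classification and cross-species site co-location
   via global alignment.
4. **TAS3 phasing** — detection of dual miR390 sites (the "two-hit" trigger),
   inference of the cleaved site, the 10/11-rule cut position, and the 21-nt
   phased tasiRNA register between the sites, including tasiRNA→ARF targeting.
5. **Origins** — Dollo parsimony (single gain at the MRCA of the lineages
   carrying a family, any number of losses below it) on a fixed eight-taxon
   land-plant cladogram.

The package ships small reference tables as fixtures: 57 conserved mature
miRNA variants in 23 families from a fern leaf sRNA library, 18 conserved
predicted target records across 11 families, a 23-family × 8-taxon
presence/absence matrix, and the cladogram used for origin mapping. All
summary numbers are recomputed from these records at runtime.

Synthetic-data generators (`fernmir.simulate`) build sRNA libraries, target
transcriptomes and TAS3 transcripts with known ground truth from a single
integer seed, so every stage of the pipeline is testable without downloads.

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

Simulate a library with three planted miRNA families, preprocess it, and
identify the families back:

```bash
fernmir simulate library --seed 11 --out-dir sim
fernmir preprocess --reads sim/reads.fastq --out tags.tsv --stats stats.json
printf '>ath-miR166a-5p\nTCGGACCAGGCTTCATTCCCC\n>ath-miR390a-5p\nAAGCTCAGGAGGGATAGCGCC\n>ath-miR156a-5p\nTTGACAGAAGATAGAGAGCAC\n' > ref.fa
fernmir identify --tags tags.tsv --reference ref.fa --out families.tsv
cat families.tsv
```

Output:

```
synthetic library written to sim
6 unique tags written to tags.tsv
3/3 families bona fide
family	n_variants	total_reads	reads_20_22	five_prime_homogeneity	has_duplex	bona_fide	rescue_used	failure_reasons
miR156	1	244	244	1.0	False	True	False
miR166	1	1159	1159	1.0	False	True	False
miR390	1	419	419	1.0	False	True	False
```

Target prediction from Python:

```python
from fernmir.io_formats import Transcript
from fernmir.targets import revcomp, scan_transcript

mir166 = "TCGGACCAGGCTTCATTCCCC"
tx = Transcript("HD-ZIP_III_mRNA",
                "AUGGCUA" * 10 + revcomp(mir166) + "GCUAAUG" * 10, cds=(3, 66))
for site in scan_transcript("pmi-miR166_v1", mir166, tx):
    print(site.mirna_name, site.transcript_id, site.interval,
          site.expectation, site.pairing)
```

```
pmi-miR166_v1 HD-ZIP_III_mRNA (70, 91) 0.0 |||||||||||||||||||||
```

## Package layout

- `fernmir.io_formats` — FASTA/FASTQ/collapsed-tag parsing, miRBase-style id
  handling, fixture loading with integrity checks
- `fernmir.preprocess` — trimming, length filter, collapsing, contaminant
  removal, RPM, length histogram
- `fernmir.identify` — reference alignment, family grouping, bona fide
  criteria, 5'-nucleotide statistics, Karlin–Altschul E-values
- `fernmir.targets` — expectation scoring, transcript scanning, region
  classification, cross-species site co-location
- `fernmir.tas3` — dual-site detection, cleavage inference, phasing register
- `fernmir.phylo` — presence/absence matrix, Dollo origin assignment, censuses
- `fernmir.simulate` — seeded ground-truth generators for all of the above
- `fernmir.report` / `fernmir.cli` — summaries and the `fernmir` command

See `docs/methods.md` for the full methods note: parameter defaults and their
rationale, coordinate conventions, numerical choices and known limitations.
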