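# cutscan

Junction-level analysis of CRISPR-Cas9 editing outcomes. `cutscan` consumes
bait→prey junction tables (one row per deduplicated editing event, as produced
by junction-capture sequencing pipelines) together with a reference genome,
plasmid and guide definition, and provides:

- **synthetic_data** — toy genomes with planted on/off-target homologs
  (controlled mismatch counts and PAM composition) and junction tables drawn
  from configurable outcome proportions, with full ground truth for testing.
- **genome_scan** — genome-wide enumeration of 23-nt guide-homologous
  candidate sites (protospacer Hamming distance + IUPAC PAM matching, both
  strands), PAM classification (NRN/NYN).
- **offtarget_calling** — off-target hotspot calling: ±20 kb proximal
  exclusion, deterministic junction-enrichment clustering, and the
  <8-mismatch / >3-junctions-at-the-cut-site hotspot rules.
- **editing_outcomes** — per-event outcome classification (uncut, indel,
  large deletion >100 bp, off-target translocation, general translocation,
  plasmid insertion), editing efficiency, fold changes between libraries, and
  plasmid-integration rates per 100k with a 100-bp binned profile.
- **consensus_analysis** — position frequency matrices, PAM second/third
  nucleotide tallies, mismatch-number distributions, cross-variant overlap
  partitions, and paired Wilcoxon signed-rank comparison.
- **cnn_predictor** — a convolutional off-target classifier over 23×4 one-hot
  encodings (conv → batch-norm → global max-pool → dense(100) → dense(23) +
  dropout → sigmoid), implemented directly on numpy with seeded, bit-
  reproducible training, plus ranked prediction and recall-at-rank curves.
- **pipeline / cli** — end-to-end orchestration with a checksummed manifest
  and byte-reproducible outputs for a fixed config + seed.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite (oracle
equivalence against a brute-force scanner, hotspot recall/precision, filter
boundary grids, binomial-interval outcome recovery, Wilcoxon exactness, CNN
quality bounds, end-to-end determinism).

## CLI

All stages are subcommands of a single entry point:

```sh
# simulate a synthetic library (genome.fa, plasmid.fa, guide.json,
# truth.json, junctions.tsv)
cutscan simulate --config sim.json --seed 1 --outdir sim/

# enumerate candidate off-target sites
cutscan scan --genome sim/genome.fa --protospacer ACGT... --pam NNN \
    --max-mm 7 --out candidates.tsv

# call off-target hotspots from junctions
cutscan call-offtargets --junctions sim/junctions.tsv \
    --candidates candidates.tsv --guide sim/guide.json --out offtargets.tsv

# classify junctions into outcome classes and summarize
cutscan classify --junctions sim/junctions.tsv --offtargets offtargets.tsv \
    --guide sim/guide.json --plasmid-length 3000 --outdir classified/

# consensus / PAM statistics (repeat --sites for multi-variant overlap)
cutscan consensus --sites offtargets_a.tsv --sites offtargets_b.tsv --outdir stats/

# CNN training and ranked prediction
cutscan train --positives offtargets.tsv --guide sim/guide.json \
    --epochs 30 --seed 1 --model-out model.json
cutscan predict --model model.json --candidates candidates.tsv --out ranked.tsv

# everything at once, from a structured config
cutscan run --config run.json
```

`run.json` holds paths, the guide definition and every threshold
(`max_mismatches=7`, `min_junctions=4`, `proximal_radius=20000`,
`ot_radius=100`, `ld_threshold=100`, `cut_window=25`, `binsize=100`), e.g.:

```json
{
  "genome": "sim/genome.fa",
  "plasmid": "sim/plasmid.fa",
  "junctions": "sim/junctions.tsv",
  "outdir": "out",
  "guide": {"protospacer": "ACGT...", "pam_pattern": "AGG",
            "chrom": "chr1", "protospacer_start": 30000, "strand": "+"},
  "seed": 1
}
```

## File formats

- Genomes/plasmids: FASTA (uncompressed).
- Junction tables: TSV with header `read_id, bait_chrom, bait_pos,
  bait_strand, prey_ref, prey_pos, prey_strand, junction_present`
  (0-based coordinates; `prey_ref` is a genome contig or `plasmid`;
  `junction_present=0` marks uncut germline records).
- Candidates and off-target calls: BED6+ TSV.
- Summaries, reports, manifests, model weights: JSON.
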