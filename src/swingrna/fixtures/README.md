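# Bundled fixture tables

These small plain-text tables are transcribed verbatim from the published study this
package operationalises; they are data, never re-derived at run time, and each file's
SHA-256 digest is pinned in `swingrna.io.FIXTURE_SHA256`.

- `table1.tsv` — secondary-structure descriptor profiles (length `n`, loop %, external-loop
  %, stem GC %, loop GC %) and cluster labels (B1/B2/D1/D2) for 72 published hairpin RNAs:
  24 simulation-generated circular RNAs ("Circ"), one template-free synthesized RNA
  ("De novo"), 29 Pandoravirus submarine MITEs, amoebal mitochondrial and Mimivirus
  rRNA-like fragments, four flavivirus 3'-5 structures, and the Dengue 5'-UTR leader with
  its surrounding sequence.
- `table2.tsv` — the same descriptors for 10 rod-shaped viroids; all cluster with D1 or D2.
- `table4.tsv` — per-swinger-rule abundances (N) and mean read lengths of putative swinger
  transcripts detected in the Mimivirus transcriptome by 454 and SOLiD sequencing. Empty
  mean cells correspond to rules with zero 454 reads.
- `mimivirus_42nt.fasta` — the 42-nt template-free RNA found in Mimivirus' transcriptome
  throughout the infection cycle.
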