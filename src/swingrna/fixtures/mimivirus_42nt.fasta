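>mimivirus_template_free_42nt persistent transcriptome RNA with no genomic template
GAGACACGCAACAGGGGATAGGCAAGGCACACAGGGGATAGG
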