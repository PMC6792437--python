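# SYNTHETIC example degenerate primers (IUPAC codes) for exercising the
# primer-audit tools. These are NOT published primer sequences; supply
# your own primer TSV (name, sequence, orientation) for real analyses.
name	sequence	orientation
synthF1	TGYGAYCCNAARGCNGA	forward
synthF2	GGHAARGGHGGHATHGGHAA	forward
synthR1	ADNGCCATCATYTCNCC	reverse
synthR2	TTYTTNGCNGCRTA	reverse
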