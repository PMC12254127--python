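"""Extract the 175-feature handcrafted descriptor for a guide.

The descriptor covers GC content, mono/di/tri-nucleotide counts on the
20-nt protospacer, six nearest-neighbor melting-temperature features, and
84 position-specific nucleotide indicators (protospacer positions 1-20
plus the variable PAM base).
"""

from casguide import SgRnaRecord, extract_features, feature_names, melting_temperature

scaffold = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCT"
record = SgRnaRecord("GACGTTACGGATCGGAAGCT" + "TGG" + scaffold, 0.72, "WT-SpCas9")

vec = extract_features(record)
named = dict(zip(feature_names(), vec))
print(f"{len(vec)} features extracted")
print(f"GC content: {named['gc_content']:.2f}")
print(f"mono counts A/C/G/T: "
      f"{[int(named[f'count_{n}']) for n in 'ACGT']}")
print(f"Tm of the protospacer: {named['tm_protospacer']:.1f} C "
      f"(GC-rich 20-mer for comparison: "
      f"{melting_temperature('GC' * 10):.1f} C)")
print(f"nucleotide adjacent to the PAM (position 20): "
      f"{[n for n in 'ACGT' if named[f'pos_20_{n}'] == 1.0][0]}")

# Counts are raw occurrences (19 dinucleotide and 18 trinucleotide windows
# on a 20-mer); Tm is the nearest-neighbor duplex estimate in Celsius.
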