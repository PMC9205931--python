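"""Encode IUPAC DNA strings as the probability matrices the classifier consumes."""

from ednacnn import encode, reverse_complement, shape_to_width

for code in ["A", "W", "N"]:
    print(f"{code} -> {encode(code)[0].tolist()}")
# Each row is a distribution over (A, C, G, T): a canonical base is one-hot,
# an ambiguity code spreads its mass uniformly over its compatible bases.

seq = "ACACCGCCCGTCACTCTW"
rc = reverse_complement(seq)
print(f"\nreverse_complement({seq}) = {rc}")

shaped = shape_to_width(encode(seq), 150)
print(f"shaped to model width: {shaped.shape}, "
      f"padding rows (all-zero): {int((shaped.sum(axis=1) == 0).sum())}")
# Reads shorter than the 150-position model width get all-zero padding rows,
# which the network can tell apart from N (uniform 0.25) positions.
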