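"""The 20-letter amino-acid alphabet and shared constants."""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Placeholder for an unknown residue. 'X' never satisfies a fixed or inclusion
#: element, fails exclusion elements conservatively (possibly-excluded -> no
#: match), and always satisfies a wildcard.
UNKNOWN = "X"

EXTENDED_SET = AA_SET | {UNKNOWN}
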