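"""Small nucleotide-sequence helpers shared across modules."""

_COMPLEMENT_DNA = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMPLEMENT_RNA = str.maketrans("ACGUNacgun", "UGCANugcan")

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

STOP_CODONS = ("TAA", "TAG", "TGA")


def complement(base: str, rna: bool = False) -> str:
    return base.translate(_COMPLEMENT_RNA if rna else _COMPLEMENT_DNA)


def revcomp(seq: str, rna: bool = False) -> str:
    """Reverse complement; alphabet chosen by `rna`."""
    table = _COMPLEMENT_RNA if rna else _COMPLEMENT_DNA
    return seq.translate(table)[::-1]


def as_dna(seq: str) -> str:
    """Uppercase and map U->T; raise on characters outside ACGTN."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def as_rna(seq: str) -> str:
    """Uppercase and map T->U; raise on characters outside ACGUN."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s
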