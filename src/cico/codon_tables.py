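"""Default codon usage table for mouse.

Frequencies are per thousand codons, rounded to one decimal, as commonly
tabulated from pooled mouse coding sequence. They serve as the default for
CAI computation and as the usage model the synthetic generator biases its
planted ORFs toward; any table in the same TSV format can be supplied
instead.
"""
from .io_formats import CodonUsageTable

MOUSE_CODON_USAGE_PER_1000 = {
    "TTT": 17.2, "TTC": 21.8, "TTA": 6.7, "TTG": 13.4,
    "CTT": 13.4, "CTC": 20.2, "CTA": 8.1, "CTG": 39.5,
    "ATT": 15.4, "ATC": 22.5, "ATA": 7.4, "ATG": 22.8,
    "GTT": 10.7, "GTC": 15.4, "GTA": 7.4, "GTG": 28.4,
    "TCT": 16.2, "TCC": 18.1, "TCA": 11.8, "TCG": 4.2,
    "CCT": 18.4, "CCC": 18.2, "CCA": 17.3, "CCG": 6.2,
    "ACT": 13.7, "ACC": 19.0, "ACA": 16.0, "ACG": 5.6,
    "GCT": 20.0, "GCC": 26.0, "GCA": 15.8, "GCG": 6.4,
    "TAT": 12.2, "TAC": 16.1,
    "CAT": 10.6, "CAC": 15.3, "CAA": 12.0, "CAG": 34.1,
    "AAT": 15.6, "AAC": 20.3, "AAA": 21.9, "AAG": 33.6,
    "GAT": 21.0, "GAC": 26.0, "GAA": 27.0, "GAG": 39.4,
    "TGT": 11.4, "TGC": 12.3, "TGG": 12.5,
    "CGT": 4.7, "CGC": 9.4, "CGA": 6.6, "CGG": 10.2,
    "AGT": 12.7, "AGC": 19.7, "AGA": 12.1, "AGG": 12.2,
    "GGT": 11.4, "GGC": 21.2, "GGA": 16.8, "GGG": 15.2,
}


def mouse_codon_usage() -> CodonUsageTable:
    return CodonUsageTable(dict(MOUSE_CODON_USAGE_PER_1000))
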