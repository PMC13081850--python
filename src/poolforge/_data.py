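"""Packaged reference data: codon usage, example ORF, motifs, 5'ss PWM.

The codon-usage fractions are approximate human values (fraction of use
among synonymous codons); only the ranking matters for the
``missense_only_first`` codon policy, which picks the most frequent
codon encoding each substitute residue.  The 5' splice-site matrix is a
9-position (positions -3..+6 around the exon/intron boundary) nucleotide
frequency model with the invariant donor GT dinucleotide at +1/+2.  The
transcription-factor binding sites are short consensus-style motifs for
three liver-enriched factors; any concrete motif sequences would do for
the library-construction logic they exercise.
"""

from __future__ import annotations

import numpy as np

# fraction of usage among synonymous codons, approximate human values
CODON_USAGE: dict[str, float] = {
    "TTT": 0.46, "TTC": 0.54,
    "TTA": 0.08, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.06, "CTG": 0.40,
    "ATT": 0.36, "ATC": 0.47, "ATA": 0.17,
    "ATG": 1.00,
    "GTT": 0.18, "GTC": 0.24, "GTA": 0.12, "GTG": 0.46,
    "TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24,
    "CCT": 0.29, "CCC": 0.32, "CCA": 0.28, "CCG": 0.11,
    "ACT": 0.25, "ACC": 0.36, "ACA": 0.28, "ACG": 0.11,
    "GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.10,
    "TAT": 0.44, "TAC": 0.56,
    "CAT": 0.42, "CAC": 0.58,
    "CAA": 0.27, "CAG": 0.73,
    "AAT": 0.47, "AAC": 0.53,
    "AAA": 0.43, "AAG": 0.57,
    "GAT": 0.46, "GAC": 0.54,
    "GAA": 0.42, "GAG": 0.58,
    "TGT": 0.45, "TGC": 0.55,
    "TGG": 1.00,
    "CGT": 0.09, "CGC": 0.18, "CGA": 0.11, "CGG": 0.20, "AGA": 0.21, "AGG": 0.21,
    "GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25,
    "TAA": 0.30, "TAG": 0.23, "TGA": 0.47,
}

_CODON_TO_AA = {
    # standard genetic code
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def usage_table() -> dict[str, list[tuple[str, float]]]:
    """Map amino acid -> [(codon, fraction), ...] ranked by frequency.

    Ties rank alphabetically by codon so the ordering is deterministic.
    """
    table: dict[str, list[tuple[str, float]]] = {}
    for codon, aa in _CODON_TO_AA.items():
        table.setdefault(aa, []).append((codon, CODON_USAGE[codon]))
    for aa in table:
        table[aa].sort(key=lambda cf: (-cf[1], cf[0]))
    return table


# B1 immunoglobulin-binding domain of streptococcal protein G, 56 residues
GB1_PEPTIDE = "MQYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"


def gb1_orf() -> str:
    """56-codon ORF encoding the GB1 domain via most-frequent human codons."""
    table = usage_table()
    return "".join(table[aa][0][0] for aa in GB1_PEPTIDE)


# consensus-style binding sites for three liver-enriched TFs
TFBS_MOTIFS = {
    "HNF4A": "AGGTCAAAGGTCA",
    "PPARA": "AACTAGGTCAAAGGTCA",
    "XBP1": "GATGACGTGTACA",
}

# 9-position 5' splice-site nucleotide frequencies (-3..+6), columns A,C,G,T
SS5_PWM_ROWS = np.array(
    [
        [0.33, 0.36, 0.19, 0.12],   # -3
        [0.61, 0.12, 0.13, 0.14],   # -2
        [0.09, 0.03, 0.80, 0.08],   # -1
        [0.0, 0.0, 1.0, 0.0],       # +1 (invariant G)
        [0.0, 0.0, 0.0, 1.0],       # +2 (invariant T)
        [0.62, 0.02, 0.34, 0.02],   # +3
        [0.68, 0.09, 0.12, 0.11],   # +4
        [0.09, 0.05, 0.78, 0.08],   # +5
        [0.17, 0.17, 0.19, 0.47],   # +6
    ]
)
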