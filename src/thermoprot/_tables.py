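"""Packaged residue-classification tables used by the descriptor encoders.

All tables partition the canonical 20-letter amino-acid alphabet; each
module-level constant is validated by the test suite (disjoint groups,
full coverage, codon counts summing to 61).
"""

from __future__ import annotations

#: Five-group physicochemical scheme used by GAAC/GDPC/GTPC/CKSAAGP.
RESIDUE_GROUPS: dict[str, str] = {
    "aliphatic": "GAVLMI",
    "aromatic": "FYW",
    "positivecharge": "KRH",
    "negativecharge": "DE",
    "uncharge": "STCPNQ",
}

#: 13 physicochemical properties, each splitting the alphabet into three
#: groups (G1/G2/G3), used by the composition/transition/distribution
#: (CTD) encoders.  The seven hydrophobicity scales are named by their
#: AAindex accession.
CTD_PROPERTIES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity_PRAM900101": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "hydrophobicity_ARGP820101": ("QSTNGDE", "RAHCKMV", "LYPFIW"),
    "hydrophobicity_ZIMJ680101": ("QNGSWTDERA", "HMCKV", "LPFYI"),
    "hydrophobicity_PONP930101": ("KPDESNQT", "GRHA", "YMFWLCVI"),
    "hydrophobicity_CASG920101": ("KDEQPSRNTG", "AHYMLV", "FIWC"),
    "hydrophobicity_ENGD860101": ("RDKENQHYP", "SGTAW", "CVLIMF"),
    "hydrophobicity_FASG890101": ("KERSQD", "NTPG", "AYHWVMFLIC"),
    "normwaalsvolume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondarystruct": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solventaccess": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

#: Conjoint-triad scheme: residues binned into 7 classes by dipole and
#: side-chain volume; used by CTriad/KSCTriad.
CONJOINT_TRIAD_CLASSES: tuple[str, ...] = (
    "AGV",
    "ILFP",
    "YMTS",
    "HNQW",
    "RK",
    "DE",
    "C",
)

#: Number of standard-genetic-code codons per residue (stop codons
#: excluded); total 61.  Feeds the theoretical dipeptide mean of DDE.
CODON_COUNTS: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2,
    "G": 4, "H": 2, "I": 3, "K": 2, "L": 6,
    "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6,
    "S": 6, "T": 4, "V": 4, "W": 1, "Y": 2,
}

CODON_TOTAL = 61
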