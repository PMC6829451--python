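"""Genetic-code-4 (mold mitochondrial) codon tables and small sequence helpers.

Fungal mitochondria translate with NCBI table 4, in which TGA encodes
tryptophan and only TAA/TAG terminate translation.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE4 = CodonTable.unambiguous_dna_by_id[4]

#: codon -> one-letter amino acid, genetic code 4 (sense codons only)
GENETIC_CODE_4: dict[str, str] = dict(_TABLE4.forward_table)

#: stop codons under genetic code 4
STOP_CODONS_4: frozenset[str] = frozenset(_TABLE4.stop_codons)

#: the 62 sense codons of code 4
SENSE_CODONS_4: tuple[str, ...] = tuple(sorted(GENETIC_CODE_4))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return a != b and (
        (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)
    )


def translate_4(cds: str) -> str:
    """Translate an in-frame CDS under code 4; '*' for stops, 'X' for ambiguity.

    A trailing partial codon is dropped.
    """
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in GENETIC_CODE_4:
            aas.append(GENETIC_CODE_4[codon])
        elif codon in STOP_CODONS_4:
            aas.append("*")
        else:
            aas.append("X")
    return "".join(aas)
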