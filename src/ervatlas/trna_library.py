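"""Synthetic labeled tRNA 3'-end 18-mers for primer-binding-site annotation.

A retroviral PBS is the reverse complement of the 3'-terminal 18 nt of a host
tRNA, and is named after that tRNA (PBS-Pro, PBS-Phe, PBS-Lys). Real tRNA
3'-end sequences are user-suppliable; the library shipped here is a synthetic
stand-in (fixed arbitrary 18-mers, plus decoys) whose only job is to give the
simulator and the annotator a shared, labeled search set. All entries end in
the universal CCA acceptor tail.
"""

from __future__ import annotations

# label -> synthetic tRNA 3'-end 18-mer (5'->3', ending in CCA)
SYNTHETIC_TRNA_3P_18MERS: dict[str, str] = {
    "Pro": "TGGCGCAGGGGTCGTCCA",
    "Phe": "ATCCGAACACGGGATCCA",
    "Lys": "GGCTCGTCAGGGTCACCA",
    # decoys: never planted by the simulator
    "Gly": "ACCGGTATCGCTAAGCCA",
    "Ser": "TTAGCAGCGGCGTAACCA",
}


def pbs_for(trna_label: str, library: dict[str, str] | None = None) -> str:
    """Plus-strand PBS sequence for a tRNA label (revcomp of the 3' 18-mer)."""
    from .genome_io import revcomp

    lib = library or SYNTHETIC_TRNA_3P_18MERS
    return revcomp(lib[trna_label])
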