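"""Standard amino-acid tables shared across modules."""

# Canonical ordering of the 20 standard residue types (alphabetical one-letter
# codes).  All 20-dim composition vectors in the package use this order.
AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residue-type label for anything that is not one of the 20 standard types
OTHER = "OTHER"


def res_type_from_3letter(name: str) -> str:
    """Map a 3-letter residue code to a one-letter type, or ``OTHER``.

    The mapping is total: any unknown or modified residue code maps to
    ``OTHER`` rather than raising.
    """
    return THREE_TO_ONE.get(name.strip().upper(), OTHER)
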