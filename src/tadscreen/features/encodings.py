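"""Amino-acid encodings: composition groups, propensity scales, motif groups.

The scales bundled here are documented proxies: disorder propensity uses a
published-style composition scale (values increase with disorder promotion),
helicity uses helix-propensity free energies plus a Fauchere-Pliska
hydrophobic-moment calculation. Users wanting predictions from dedicated
disorder/helicity programs can plug their outputs in as custom encodings.
"""

from __future__ import annotations

import json
from importlib import resources

#: Composition output order for the 20 standard amino acids.
AA_ORDER = "IVLAFWYGSPKRHDETQNCM"

#: Overlapping residue groups for grouped composition features.
AA_GROUPS = {
    "aliphatic": "IVLA",
    "aromatic": "FWY",
    "branching": "VIT",
    "charged": "KRHDE",
    "negative": "DE",
    "phosphorylatable": "STY",
    "polar": "RKDEQNY",
    "hydrophobic": "VILFWCM",
    "positive": "KRH",
    "sulfur": "MC",
    "tiny": "GASP",
}

#: Mini-motif groups: three fine (chemistry-specific) and two coarse.
#: "non-polar" is the complement of the polar group over the 20 residues.
MINIMOTIF_GROUPS = {
    "negative": "DE",
    "positive": "KRH",
    "aromatic": "FWY",
    "polar": "RKDEQNY",
    "nonpolar": "".join(sorted(set(AA_ORDER) - set("RKDEQNY"))),
}
FINE_GROUPS = ("negative", "positive", "aromatic")
COARSE_GROUPS = ("polar", "nonpolar")

#: Disorder-promoting propensity scale (TOP-IDP style: order-promoting
#: residues negative, disorder-promoting positive). Used as a mean-over-
#: sequence proxy, min-max normalized to [0, 1].
DISORDER_SCALE = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": 0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "S": 0.341, "K": 0.586, "E": 0.736, "P": 0.987,
}

#: Helix-propensity free energies (kcal/mol, alanine = 0; lower = more
#: helical). The helicity proxy is 1 minus the normalized mean.
HELIX_PROPENSITY = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}

#: Fauchere-Pliska hydrophobicity, used for the helical hydrophobic moment.
FP_HYDROPHOBICITY = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

#: Side-chain and terminal pKa values (EMBOSS set). pI depends on the table
#: choice; this one is recorded in the catalog metadata.
PKA_SIDECHAIN = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
PKA_NTERM = 8.6
PKA_CTERM = 3.6
POSITIVE_SIDECHAINS = ("H", "K", "R")
NEGATIVE_SIDECHAINS = ("C", "D", "E", "Y")

HYDROPHOBIC_SET = set("VILFWCM")


def load_ninetad_patterns() -> list[str]:
    """Load the four nine-residue TAD motif regular expressions.

    The bundled file is a synthetic reconstruction of the published motif
    variants (see its docstring); a missing file is a hard configuration
    error rather than a silently absent feature.
    """
    ref = resources.files("tadscreen.data").joinpath(
        "ninetad_patterns_synthetic.json"
    )
    try:
        payload = json.loads(ref.read_text())
    except FileNotFoundError as exc:  # pragma: no cover - packaging error
        raise RuntimeError(
            "nine-residue TAD pattern file missing from tadscreen.data"
        ) from exc
    patterns = payload["patterns"]
    if len(patterns) != 4:
        raise RuntimeError("expected exactly four nine-residue TAD patterns")
    return patterns
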