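"""Published benchmark sample definitions.

Accession lists and class labels of the three protein families commonly
used to benchmark alignment-free similarity methods: seven beta globins,
nine mitochondrial NADH dehydrogenase subunit 5 (ND5) sequences, and 29
coronavirus spike glycoproteins spanning classes I, II, III and the
SARS-CoVs.  Only metadata lives here; the sequences themselves must be
fetched from NCBI (see ``scripts/fetch_published.py``) — the library never
requires network access.
"""

from __future__ import annotations

#: (species, accession) in sample order; lengths 121-147.
BETA_GLOBIN: tuple[tuple[str, str], ...] = (
    ("Human", "AAA16334"),
    ("Chimpanzee", "CAA26204"),
    ("Gorilla", "CAA43421"),
    ("Mouse", "CAA24101"),
    ("Rat", "CAA29887"),
    ("Gallus", "CAA23700"),
    ("Opossum", "AAA30976"),
)

#: (species, accession) in sample order; lengths 602-610.
ND5: tuple[tuple[str, str], ...] = (
    ("Human", "AP_000649"),
    ("Gorilla", "NP_008222"),
    ("Pigmy chimpanzee", "NP_008209"),
    ("Common chimpanzee", "NP_008196"),
    ("Fin whale", "NP_006899"),
    ("Blue whale", "NP_007066"),
    ("Rat", "AP_004902"),
    ("Mouse", "NP_904338"),
    ("Opossum", "NP_007105"),
)

#: (abbreviation, accession, class label) in sample order; lengths 1162-1447.
SPIKE: tuple[tuple[str, str, str], ...] = (
    ("TGEVG", "CAB91145", "I"),
    ("TGEV", "NP058424", "I"),
    ("PEDVC", "AAK38656", "I"),
    ("PEDV", "NP598310", "I"),
    ("HCoVOC43", "NP937950", "II"),
    ("BCoVE", "AAK83356", "II"),
    ("BCoVL", "AAL57308", "II"),
    ("BCoVM", "AAA66399", "II"),
    ("BCoVQ", "AAL40400", "II"),
    ("MHVA", "AAB86819", "II"),
    ("MHVJHM", "YP_209233", "II"),
    ("MHVP", "AAF69334", "II"),
    ("MHVM", "AAF69344", "II"),
    ("IBVBJ", "AAP92675", "III"),
    ("IBVC", "AAS00080", "III"),
    ("IBV", "NP_040831", "III"),
    ("GD03T0013", "AAS10463", "SARS-CoVs"),
    ("PC4127", "AAU93318", "SARS-CoVs"),
    ("PC4137", "AAV49720", "SARS-CoVs"),
    ("PC4205", "AAU93319", "SARS-CoVs"),
    ("civet007", "AAU04646", "SARS-CoVs"),
    ("civet010", "AAU04649", "SARS-CoVs"),
    ("A022", "AAV91631", "SARS-CoVs"),
    ("GD01", "AAP51227", "SARS-CoVs"),
    ("GZ02", "AAS00003", "SARS-CoVs"),
    ("BJ01", "AAP30030", "SARS-CoVs"),
    ("FRA", "AAP50485", "SARS-CoVs"),
    ("TOR2", "AAP41037", "SARS-CoVs"),
    ("TaiwanTC1", "AAQ01597", "SARS-CoVs"),
)


def spike_class_labels() -> dict[str, str]:
    """Class label keyed by spike abbreviation."""
    return {abbr: cls for abbr, _, cls in SPIKE}
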