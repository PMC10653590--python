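"""Canonical olfactory-receptor (OR) family identifiers.

Mammalian OR genes fall into 13 well-supported monophyletic families.
Class I ("fish-like", mostly water-borne odorant binding) comprises
families 51, 52, 55 and 56; the remaining nine families form class II.
Hyphenated identifiers (e.g. ``"1-3-7"``) denote monophyletic clusters of
the historically separate numbered families.
"""

FAMILIES: tuple[str, ...] = (
    "51", "52", "55", "56",
    "1-3-7", "2-13", "4", "5-8-9", "6", "10", "11", "12", "14",
)

CLASS_I: tuple[str, ...] = ("51", "52", "55", "56")
CLASS_II: tuple[str, ...] = tuple(f for f in FAMILIES if f not in CLASS_I)

UNASSIGNED = "unassigned"
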