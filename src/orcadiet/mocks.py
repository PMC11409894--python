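"""Mock-community designs used to calibrate amplification bias.

Two DNA mixtures of vouchered prey tissue, combined in pre-determined
proportions, are sequenced alongside the faecal samples: a *general* control
spanning the dominant prey guilds (salmonid, gadiform-like, forage fish,
flatfish) and a *salmonid-specific* control resolving bias among the
Oncorhynchus / Salmo species that dominate resident killer whale diet.
"""

from __future__ import annotations

# control 1: general prey mixture (proportions of input DNA)
GENERAL_CONTROL: dict[str, float] = {
    "chinook": 0.15,
    "lingcod": 0.40,
    "herring": 0.05,
    "halibut": 0.40,
}

# control 2: salmonid-specific mixture
SALMONID_CONTROL: dict[str, float] = {
    "chinook": 0.20,
    "coho": 0.10,
    "chum": 0.20,
    "rainbow_trout": 0.10,
    "sockeye": 0.10,
    "pink": 0.10,
    "atlantic_salmon": 0.20,
}

#: Union of species present in either control, sorted for stable ordering.
MOCK_SPECIES: tuple[str, ...] = tuple(
    sorted(set(GENERAL_CONTROL) | set(SALMONID_CONTROL))
)
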