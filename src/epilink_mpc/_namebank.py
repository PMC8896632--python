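"""Synthetic name/place banks for the data generator.

Every list here is synthetic: a small core of common German/English-style
names for realism, extended deterministically with pronounceable
syllable-built names so the banks are large enough for population-scale
sampling without shipping real-world microdata.  Sampling weights follow
a shifted power law ``p_i ~ 1/(i + shift)``, whose collision probability
(the chance two random draws agree) is what the default configuration's
frequency parameters encode.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_GIVEN_CORE = [
    "PETER", "MICHAEL", "THOMAS", "ANDREAS", "WOLFGANG", "KLAUS", "JUERGEN",
    "MARIA", "URSULA", "MONIKA", "PETRA", "ELISABETH", "SABINE", "RENATE",
    "HANS", "WERNER", "CHRISTIAN", "STEFAN", "MARTIN", "FRANK", "MARKUS",
    "ANNA", "KARIN", "HELGA", "INGRID", "ERIKA", "CLAUDIA", "SUSANNE",
    "JULIA", "KATHARINA", "LAURA", "SOPHIE", "MARIE", "LENA", "EMMA",
    "PAUL", "FELIX", "LUKAS", "JONAS", "DAVID", "SIMON", "TOBIAS",
    "SARAH", "LISA", "NINA", "JANA", "EVA", "IRIS", "CARLA", "IDA",
]

_SURNAME_CORE = [
    "MUELLER", "SCHMIDT", "SCHNEIDER", "FISCHER", "WEBER", "MEYER",
    "WAGNER", "BECKER", "SCHULZ", "HOFFMANN", "SCHAEFER", "KOCH",
    "BAUER", "RICHTER", "KLEIN", "WOLF", "SCHROEDER", "NEUMANN",
    "SCHWARZ", "ZIMMERMANN", "BRAUN", "KRUEGER", "HOFMANN", "HARTMANN",
    "LANGE", "SCHMITT", "WERNER", "KRAUSE", "MEIER", "LEHMANN",
    "HUBER", "MAYER", "HERRMANN", "KOEHLER", "WALTER", "KOENIG",
    "SCHULZE", "FUCHS", "KAISER", "LANG", "WEISS", "PETERS",
]

_CITY_CORE = [
    "BERLIN", "HAMBURG", "MUENCHEN", "KOELN", "FRANKFURT", "STUTTGART",
    "DUESSELDORF", "LEIPZIG", "DORTMUND", "ESSEN", "BREMEN", "DRESDEN",
    "HANNOVER", "NUERNBERG", "DUISBURG", "BOCHUM", "WUPPERTAL",
    "BIELEFELD", "BONN", "MUENSTER", "MANNHEIM", "KARLSRUHE", "AUGSBURG",
    "WIESBADEN", "MAINZ", "ERFURT", "KASSEL", "ROSTOCK", "POTSDAM",
    "OLDENBURG",
]

# Spelling diversity matters as much as value frequencies: unrelated real
# surnames overlap in at most a short affix, so generated names draw from
# a wide syllable inventory with variable length and only an occasional
# family-name suffix — otherwise unrelated names would share large bigram
# chunks and show unrealistically high Dice similarity.
_ONSETS = ["B", "BL", "BR", "C", "D", "DR", "F", "FL", "FR", "G", "GL",
           "GR", "H", "J", "K", "KL", "KR", "L", "M", "N", "P", "PF",
           "PL", "PR", "Q", "R", "S", "SCH", "SL", "SP", "ST", "T", "TH",
           "TR", "V", "W", "X", "Z", "ZW", ""]
_NUCLEI = ["A", "E", "I", "O", "U", "Y", "AA", "AI", "AU", "EA", "EE",
           "EI", "EO", "EU", "IA", "IE", "IO", "OA", "OE", "OI", "OO",
           "OU", "UE", "UI"]
_CODAS = ["", "B", "CH", "CK", "D", "F", "G", "H", "K", "L", "LL", "LM",
          "LS", "LT", "M", "N", "NG", "NN", "NS", "NT", "NZ", "P", "R",
          "RG", "RM", "RN", "RS", "RT", "RZ", "S", "SS", "ST", "T", "TT",
          "TZ", "W", "X", "Z"]
_SUFFIX = ["ER", "MANN", "BERG", "FELD", "STEIN", "HOF", "BACH", "THAL"]


def _next(state: int) -> int:
    return (state * 1103515245 + 12345) & 0x7FFFFFFF


def _syllable(state: int) -> tuple[str, int]:
    state = _next(state)
    onset = _ONSETS[state % len(_ONSETS)]
    state = _next(state)
    nucleus = _NUCLEI[state % len(_NUCLEI)]
    state = _next(state)
    coda = _CODAS[state % len(_CODAS)]
    return onset + nucleus + coda, state


def _built_name(index: int, suffixed: bool) -> str:
    state = (index * 2654435761 + 97) & 0x7FFFFFFF
    state = _next(state)
    n_syllables = 1 + state % 3
    parts = []
    for _ in range(n_syllables):
        part, state = _syllable(state)
        parts.append(part)
    name = "".join(parts)
    state = _next(state)
    if suffixed and state % 10 < 3:  # occasional family-name suffix
        name += _SUFFIX[state % len(_SUFFIX)]
    return name


def _extend(core: list[str], total: int, suffixed: bool) -> list[str]:
    names = list(core)
    seen = set(names)
    index = 0
    while len(names) < total:
        candidate = _built_name(index, suffixed)
        index += 1
        if candidate not in seen and 3 <= len(candidate) <= 14:
            seen.add(candidate)
            names.append(candidate)
    return names


def _powerlaw_weights(n: int, shift: int) -> np.ndarray:
    w = 1.0 / (np.arange(1, n + 1) + shift)
    return w / w.sum()


@lru_cache(maxsize=None)
def given_names() -> tuple[tuple[str, ...], tuple[float, ...]]:
    names = _extend(_GIVEN_CORE, 600, suffixed=False)
    return tuple(names), tuple(_powerlaw_weights(600, 20))


@lru_cache(maxsize=None)
def surnames() -> tuple[tuple[str, ...], tuple[float, ...]]:
    names = _extend(_SURNAME_CORE, 3000, suffixed=True)
    return tuple(names), tuple(_powerlaw_weights(3000, 50))


@lru_cache(maxsize=None)
def cities() -> tuple[tuple[str, ...], tuple[float, ...]]:
    names = _extend(_CITY_CORE, 500, suffixed=True)
    return tuple(names), tuple(_powerlaw_weights(500, 10))


@lru_cache(maxsize=None)
def city_zip_codes() -> tuple[tuple[str, ...], ...]:
    """Five-digit ZIP codes per city, roughly proportional to city size.

    Real postal systems subdivide large cities into many codes while small
    towns share one; the resulting ZIP collision probability (~1e-3) is
    far below the city collision probability, as in real microdata.
    """
    names, weights = cities()
    zips = []
    state = 99991
    used = set()
    for i, p in enumerate(weights):
        n_codes = max(1, round(1000 * p))
        codes = []
        for _ in range(n_codes):
            state = (state * 1103515245 + 12345) & 0x7FFFFFFF
            code = f"{10000 + state % 89999:05d}"
            while code in used:
                state = (state * 1103515245 + 12345) & 0x7FFFFFFF
                code = f"{10000 + state % 89999:05d}"
            used.add(code)
            codes.append(code)
        zips.append(tuple(codes))
    return tuple(zips)


def collision_probability(weights) -> float:
    """Chance two independent draws agree: sum of squared weights."""
    w = np.asarray(weights)
    return float(np.sum(w * w))
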