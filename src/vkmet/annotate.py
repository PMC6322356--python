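"""Exact-mass metabolite annotation.

Screened features are annotated by computing each library compound's
monoisotopic mass from its elemental formula, deriving theoretical adduct
m/z values ([M+H]+ in positive mode; [M-H]- and the formate adduct
[M+FA-H]- in negative mode) and accepting matches within a signed ppm
tolerance (default 10 ppm).  The charge carrier is the proton
(1.00727646 Da), so electron mass is accounted for implicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CompoundRecord",
    "MatchResult",
    "MONOISOTOPIC",
    "PROTON_MASS",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "match_library",
]

# monoisotopic atomic masses, Da
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

PROTON_MASS = 1.00727646
FORMIC_ACID_MASS = 46.0054793  # CH2O2

# adduct -> (mass shift from neutral monoisotopic mass, polarity)
ADDUCTS = {
    "M+H": (PROTON_MASS, "pos"),
    "M-H": (-PROTON_MASS, "neg"),
    "M+FA-H": (FORMIC_ACID_MASS - PROTON_MASS, "neg"),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class CompoundRecord:
    name: str
    formula: str
    adducts: tuple[str, ...]
    kegg_id: str = ""
    pathway_names: tuple[str, ...] = ()


@dataclass
class MatchResult:
    feature_id: str
    compound: CompoundRecord
    adduct: str
    theoretical_mz: float
    ppm_error: float
    annotated: bool = True
    alternatives: list = field(default_factory=list)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a CHNOPS elemental formula like ``C26H45NO7S`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise ValueError(f"unsupported element {el!r} in {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a CHNOPS formula; empty formula is 0 Da."""
    if not formula:
        import warnings

        warnings.warn("empty formula; mass 0")
        return 0.0
    return sum(MONOISOTOPIC[el] * n for el, n in parse_formula(formula).items())


def adduct_mz(mass: float, adduct: str, extra_adducts: dict | None = None) -> float:
    """Theoretical m/z of an adduct of a neutral monoisotopic mass."""
    table = dict(ADDUCTS)
    if extra_adducts:
        table.update(extra_adducts)
    if adduct not in table:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(table)}")
    return mass + table[adduct][0]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def read_library(path) -> list[CompoundRecord]:
    """Read a compound library TSV: ``id/name  formula  adducts  kegg_id  pathways``.

    ``adducts`` is comma-separated; ``pathways`` semicolon-separated.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    recs = []
    for r in df.itertuples():
        recs.append(
            CompoundRecord(
                name=str(r.name),
                formula=str(r.formula),
                adducts=tuple(s.strip() for s in str(r.adducts).split(",")),
                kegg_id=str(getattr(r, "kegg_id", "")),
                pathway_names=tuple(
                    s.strip() for s in str(getattr(r, "pathways", "")).split(";") if s.strip()
                ),
            )
        )
    return recs


def match_library(
    features: list[tuple[str, float, str]],
    library: list[CompoundRecord],
    tol_ppm: float = 10.0,
) -> list[MatchResult]:
    """Match (feature_id, observed m/z, polarity) queries against a library.

    Only adducts of the query's polarity are considered ('pos' -> M+H,
    'neg' -> M-H and M+FA-H).  All candidate matches within ``tol_ppm``
    (inclusive) are returned per feature, sorted by absolute ppm error;
    isomeric library entries are returned as co-equal candidates.  Features
    without any match come back with ``annotated=False``.
    """
    out: list[MatchResult] = []
    for fid, mz, mode in features:
        candidates: list[MatchResult] = []
        for comp in library:
            mass = monoisotopic_mass(comp.formula)
            for add in comp.adducts:
                if add not in ADDUCTS or ADDUCTS[add][1] != mode:
                    continue
                theo = adduct_mz(mass, add)
                err = ppm_error(mz, theo)
                if abs(err) <= tol_ppm:
                    candidates.append(MatchResult(fid, comp, add, theo, err))
        candidates.sort(key=lambda r: (abs(r.ppm_error), r.compound.name, r.adduct))
        if candidates:
            best = candidates[0]
            best.alternatives = candidates[1:]
            out.append(best)
        else:
            out.append(
                MatchResult(fid, CompoundRecord("", "", ()), "", float("nan"),
                            float("nan"), annotated=False)
            )
    return out
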