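"""Monoisotopic mass arithmetic and the lipid marker panel.

Negative-mode REIMS fingerprints report deprotonated ions [M-H]-. The ion
mass used throughout this package is the neutral monoisotopic mass minus one
hydrogen *atom* mass (no electron-mass term): that convention reproduces the
published accurate masses of the marker panel to <=5e-4 Da for 14 of the 18
records. The four records that disagree with every standard convention by
more than 5e-4 Da are shipped verbatim but flagged ``mass_discrepant``; for
annotation the printed value stays authoritative, the computed one is used
for validation only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ATOMIC_MASSES",
    "HYDROGEN_MASS",
    "Formula",
    "parse_formula",
    "formula_to_text",
    "monoisotopic_mass",
    "mh_ion_mass",
    "MarkerRecord",
    "build_marker_panel",
    "annotate_bins",
]

#: Most-abundant-isotope atomic masses (Da). Carbon-12 defines the scale.
ATOMIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
}

HYDROGEN_MASS = ATOMIC_MASSES["H"]

#: element -> count map, e.g. {"C": 22, "H": 32, "O": 2}
Formula = dict

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formulas or unknown element symbols."""


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style molecular formula such as ``"C22H32O2"``.

    Repeated element symbols accumulate. Counts default to 1.

    Raises
    ------
    FormulaError
        If the string contains anything but known element symbols with
        optional positive integer counts.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    pos = 0
    counts: Formula = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(num) if num else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at {text[pos:]!r}")
    return counts


def formula_to_text(f: Formula) -> str:
    """Canonical Hill-order text: C first, then H, then other elements
    alphabetically; count 1 is left implicit."""
    order = [e for e in ("C", "H") if e in f]
    order += sorted(e for e in f if e not in ("C", "H"))
    out = []
    for e in order:
        n = f[e]
        out.append(e if n == 1 else f"{e}{n}")
    return "".join(out)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of most-abundant-isotope atomic masses (Da)."""
    try:
        return sum(ATOMIC_MASSES[e] * n for e, n in f.items())
    except KeyError as exc:  # pragma: no cover - parse_formula guards this
        raise FormulaError(f"unknown element {exc}") from exc


def mh_ion_mass(f: Formula) -> float:
    """Deprotonated-ion ([M-H]-) mass: neutral mass minus one H atom.

    Raises
    ------
    FormulaError
        If the formula contains no hydrogen to lose.
    """
    if f.get("H", 0) < 1:
        raise FormulaError("cannot deprotonate a hydrogen-free formula")
    return monoisotopic_mass(f) - HYDROGEN_MASS


# ---------------------------------------------------------------------------
# Marker panel


@dataclass(frozen=True)
class MarkerRecord:
    """One row of the shipped lipid marker panel.

    ``accurate_mass`` is the published value and stays authoritative for bin
    annotation; ``computed_mass`` is ``mh_ion_mass(formula)`` and is used for
    validation. ``mass_discrepant`` marks records where the two disagree by
    more than ``MASS_TOLERANCE``; ``bin_discrepant`` marks records whose
    published bin label does not contain the published accurate mass under
    0.2 Da binning from m/z 100.
    """

    bin_label: float
    formula: str
    accurate_mass: float
    lipid_id: str
    lipid_class: str
    computed_mass: float = field(default=float("nan"), compare=False)
    mass_discrepant: bool = field(default=False, compare=False)
    bin_discrepant: bool = field(default=False, compare=False)


MASS_TOLERANCE = 5e-4

# (bin label, formula, published accurate [M-H]- mass, lipid id, class)
_PANEL_ROWS = [
    (127.1, "C7H12O2", 127.0759, "FA 7:1", "FA0103"),
    (239.1, "C15H28O2", 239.2011, "FA 15:1", "FA0103"),
    (277.3, "C18H30O2", 277.2168, "FA 18:3", "FA0103"),
    (301.3, "C20H30O2", 301.2168, "FA 20:5", "FA0103"),
    (327.3, "C22H32O2", 327.2324, "FA 22:6", "FA0103"),
    (337.3, "C22H42O2", 337.3107, "FA 22:1", "FA0103"),
    (255.3, "C16H32O2", 255.2324, "FA 16:0", "FA0102"),
    (279.3, "C18H32O2", 279.2330, "FA 18:2", "FA0102"),
    (281.3, "C18H34O2", 281.2481, "FA 18:1", "FA0102"),
    (309.3, "C20H38O2", 309.2794, "FA 20:1", "FA0102"),
    (280.3, "C14H23N3O3", 280.1667, "amide C14H23N3O3", "primary amide"),
    (282.3, "C18H37NO", 282.2797, "amide C18H37NO", "primary amide"),
    (128.1, "C7H15NO", 128.1075, "NA 7:0", "FA0802"),
    (222.1, "C14H25NO", 222.1863, "NA 14:2", "FA0802"),
    (338.3, "C20H37NO3", 338.2701, "NA 20:2", "FA0802"),
    (745.5, "C40H75O10P", 745.5020, "PG 34:2", "GP0401"),
    (790.5, "C45H78NO8P", 790.5387, "PC 37:6", "GP0101"),
    (909.5, "C60H94O6", 909.6972, "TG 57:11", "GL0301"),
]


def _containing_bin_label(mz: float, lo: float = 100.0, width: float = 0.2) -> float:
    idx = int((mz - lo) // width)
    return round(lo + (idx + 0.5) * width, 1)


def build_marker_panel() -> list[MarkerRecord]:
    """The 18-record marker panel with discrepancy flags recomputed."""
    panel = []
    for bin_label, formula, acc, lid, lclass in _PANEL_ROWS:
        calc = mh_ion_mass(parse_formula(formula))
        panel.append(
            MarkerRecord(
                bin_label=bin_label,
                formula=formula,
                accurate_mass=acc,
                lipid_id=lid,
                lipid_class=lclass,
                computed_mass=calc,
                mass_discrepant=abs(calc - acc) > MASS_TOLERANCE,
                bin_discrepant=_containing_bin_label(acc) != bin_label,
            )
        )
    return panel


class AmbiguityError(ValueError):
    """A marker matched more than one bin (tolerance too wide)."""


def annotate_bins(
    bin_labels,
    panel: list[MarkerRecord] | None = None,
    tolerance: float = 0.1,
) -> dict[float, MarkerRecord]:
    """Attach each marker to the unique bin whose labelled interval
    ``[label - tolerance, label + tolerance)`` contains its published
    accurate mass.

    Parameters
    ----------
    bin_labels : iterable of float (or numeric strings)
        Unique bin-center labels, e.g. the 5500-bin axis.
    panel : list of MarkerRecord, optional
        Defaults to the shipped panel.
    tolerance : float
        Half-width of the labelled interval; 0.1 Da matches 0.2 Da bins.

    Returns
    -------
    dict mapping matched bin label -> MarkerRecord. Unmatched bins are
    simply absent.
    """
    labels = [float(b) for b in bin_labels]
    if len(set(labels)) != len(labels):
        raise ValueError("bin labels must be unique")
    if panel is None:
        panel = build_marker_panel()
    out: dict[float, MarkerRecord] = {}
    for rec in panel:
        hits = [
            b for b in labels if b - tolerance <= rec.accurate_mass < b + tolerance
        ]
        if len(hits) > 1:
            raise AmbiguityError(
                f"marker {rec.lipid_id} at {rec.accurate_mass} matches bins {hits}; "
                "reduce the tolerance"
            )
        if hits:
            out[hits[0]] = rec
    return out
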