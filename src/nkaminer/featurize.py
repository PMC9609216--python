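"""Protein attribute census: composition, physicochemistry and ratios.

Each sequence is summarised into a fixed, versioned inventory of numeric
attributes: length, molecular weight, aliphatic index, isoelectric point;
counts and frequencies of the 20 residues, the 400 ordered dipeptides, the
five elements (C, H, N, O, S) and four residue classes (hydrophobic,
hydrophilic, positive, negative); and the 380 ordered residue-count
ratios.  That totals 1,242 attributes under inventory version
``census-1242-v1``.

Conventions, stated once:

* Ambiguity letters (B, Z, X, U, O) are excluded from residue, dipeptide,
  element and ratio counts; they do count toward ``length`` and they
  contribute documented average masses to the molecular weight.
* Frequencies are fractions in [0, 1] (residues over standard-residue
  count, dipeptides over counted windows, elements over total atoms).
* Zero-denominator ratios fall back to the numerator count, keeping all
  attribute values finite and monotone in the numerator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AttributeTable, ProteinRecord, STANDARD_AA

INVENTORY_VERSION = "census-1242-v1"

AA = tuple(STANDARD_AA)  # alphabetical
DIPEPTIDES = tuple(a + b for a in AA for b in AA)
ELEMENTS = ("C", "H", "N", "O", "S")

# Residue class sets (Kyte-Doolittle sign for hydro classes).
HYDROPHOBIC = frozenset("AVLIMFWC")
HYDROPHILIC = frozenset("RKDENQHSTY")
POSITIVE = frozenset("KRH")
NEGATIVE = frozenset("DE")
CLASSES: dict[str, frozenset] = {
    "hydrophilic": HYDROPHILIC,
    "hydrophobic": HYDROPHOBIC,
    "negative": NEGATIVE,
    "positive": POSITIVE,
}

# Atom counts (C, H, N, O, S) of the free amino acids.
RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),
    "C": (3, 7, 1, 2, 1),
    "D": (4, 7, 1, 4, 0),
    "E": (5, 9, 1, 4, 0),
    "F": (9, 11, 1, 2, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "N": (4, 8, 2, 3, 0),
    "P": (5, 9, 1, 2, 0),
    "Q": (5, 10, 2, 3, 0),
    "R": (6, 14, 4, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
}

# Average residue masses (free amino acid minus water), Da.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.015
# Ambiguity letters: B = Asn/Asp average, Z = Gln/Glu average, X = mean of
# the 20 standard residues, U = selenocysteine, O = pyrrolysine.
AMBIGUOUS_MASS: dict[str, float] = {
    "B": (RESIDUE_MASS["N"] + RESIDUE_MASS["D"]) / 2.0,
    "Z": (RESIDUE_MASS["Q"] + RESIDUE_MASS["E"]) / 2.0,
    "X": sum(RESIDUE_MASS.values()) / 20.0,
    "U": 150.0388,
    "O": 237.3018,
}

# EMBOSS pKa set for the isoelectric point.
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"H": 6.5, "K": 10.8, "R": 12.5}
PKA_NEGATIVE = {"C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}


def build_inventory() -> list[str]:
    """Ordered attribute names for inventory ``census-1242-v1``.

    Family order: physicochemical block, residue counts/freqs, dipeptide
    counts/freqs, element counts/freqs, class counts/freqs, ratios;
    alphabetical within each family.
    """
    names: list[str] = ["length", "molecular_weight", "aliphatic_index", "isoelectric_point"]
    names += [f"count_{a}" for a in AA]
    names += [f"freq_{a}" for a in AA]
    names += [f"count_{d}" for d in DIPEPTIDES]
    names += [f"freq_{d}" for d in DIPEPTIDES]
    names += [f"count_element_{e}" for e in ELEMENTS]
    names += [f"freq_element_{e}" for e in ELEMENTS]
    names += [f"count_{c}" for c in sorted(CLASSES)]
    names += [f"freq_{c}" for c in sorted(CLASSES)]
    names += [f"ratio_{x}_{y}" for x in AA for y in AA if x != y]
    assert len(names) == 1242
    return names


INVENTORY: list[str] = build_inventory()


def compute_residue_attributes(sequence: str) -> dict[str, float]:
    """Counts/frequencies of the 20 residues and the four residue classes.

    Frequencies use the number of standard residues as denominator;
    ambiguity letters are excluded.  A sequence with no standard residue
    is an error.
    """
    n_std = sum(1 for c in sequence if c in RESIDUE_MASS)
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    out: dict[str, float] = {}
    for a in AA:
        c = sequence.count(a)
        out[f"count_{a}"] = float(c)
        out[f"freq_{a}"] = c / n_std
    for name, members in CLASSES.items():
        c = sum(1 for ch in sequence if ch in members)
        out[f"count_{name}"] = float(c)
        out[f"freq_{name}"] = c / n_std
    return out


def compute_dipeptides(sequence: str) -> dict[str, float]:
    """Overlapping width-2 window counts over consecutive standard residues.

    Windows touching an ambiguity letter are skipped; frequencies divide
    by the number of counted windows (0 windows -> all frequencies 0).
    """
    counts = dict.fromkeys(DIPEPTIDES, 0)
    windows = 0
    for i in range(len(sequence) - 1):
        pair = sequence[i : i + 2]
        if pair[0] in RESIDUE_MASS and pair[1] in RESIDUE_MASS:
            counts[pair] += 1
            windows += 1
    out: dict[str, float] = {}
    for d in DIPEPTIDES:
        out[f"count_{d}"] = float(counts[d])
        out[f"freq_{d}"] = counts[d] / windows if windows else 0.0
    return out


def compute_elements(sequence: str) -> dict[str, float]:
    """Elemental composition (C, H, N, O, S) of the polypeptide.

    Sum of free-amino-acid formulas over standard residues minus one
    water per peptide bond between adjacent standard residues; element
    frequency = element count / total atoms.
    """
    totals = np.zeros(5, dtype=np.int64)
    for ch in sequence:
        f = RESIDUE_FORMULA.get(ch)
        if f is not None:
            totals += np.asarray(f)
    bonds = sum(
        1
        for i in range(len(sequence) - 1)
        if sequence[i] in RESIDUE_MASS and sequence[i + 1] in RESIDUE_MASS
    )
    # each peptide bond releases H2O: 2 H and 1 O
    totals[1] -= 2 * bonds
    totals[3] -= bonds
    atoms = int(totals.sum())
    out: dict[str, float] = {}
    for e, c in zip(ELEMENTS, totals):
        out[f"count_element_{e}"] = float(c)
        out[f"freq_element_{e}"] = (c / atoms) if atoms else 0.0
    return out


def net_charge(sequence: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (EMBOSS pKa set)."""
    pos = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    neg = 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for ch in sequence:
        if ch in PKA_POSITIVE:
            pos += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[ch]))
        elif ch in PKA_NEGATIVE:
            neg += 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[ch] - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_physchem(sequence: str) -> dict[str, float]:
    """length, molecular weight (Da), aliphatic index, isoelectric point."""
    n_std = sum(1 for c in sequence if c in RESIDUE_MASS)
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    mw = WATER_MASS
    for ch in sequence:
        mw += RESIDUE_MASS.get(ch) or AMBIGUOUS_MASS[ch]
    mole = {a: 100.0 * sequence.count(a) / n_std for a in ("A", "V", "I", "L")}
    ai = mole["A"] + 2.9 * mole["V"] + 3.9 * (mole["I"] + mole["L"])
    return {
        "length": float(len(sequence)),
        "molecular_weight": mw,
        "aliphatic_index": ai,
        "isoelectric_point": isoelectric_point(sequence),
    }


def compute_ratios(residue_counts: Mapping[str, float]) -> dict[str, float]:
    """380 ordered residue-count ratios.

    ratio_X_Y = count_X / count_Y; a zero denominator falls back to
    count_X (equivalent to max(count_Y, 1)).
    """
    out: dict[str, float] = {}
    for x in AA:
        cx = residue_counts[f"count_{x}"]
        for y in AA:
            if x == y:
                continue
            cy = residue_counts[f"count_{y}"]
            out[f"ratio_{x}_{y}"] = cx / cy if cy > 0 else cx
    return out


def featurize_sequence(sequence: str) -> dict[str, float]:
    res = compute_residue_attributes(sequence)
    row = compute_physchem(sequence)
    row.update(res)
    row.update(compute_dipeptides(sequence))
    row.update(compute_elements(sequence))
    row.update(compute_ratios(res))
    return row


def featurize_all(records: Sequence[ProteinRecord]) -> AttributeTable:
    """Assemble the attribute table, one row per record, inventory order."""
    if not records:
        raise ValueError("no records to featurize")
    rows = []
    for rec in records:
        try:
            rows.append(featurize_sequence(rec.sequence))
        except ValueError as exc:
            raise ValueError(f"featurization failed for {rec.id!r}: {exc}") from exc
    data = pd.DataFrame(rows, index=[r.id for r in records], columns=INVENTORY)
    labels = pd.DataFrame(
        {
            "group": [r.group or "" for r in records],
            "isoform": [r.isoform or "" for r in records],
        },
        index=data.index,
    )
    return AttributeTable(data=data, labels=labels, inventory_version=INVENTORY_VERSION)
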