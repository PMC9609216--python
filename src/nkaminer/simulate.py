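"""Synthetic protein families with planted, fully known signal.

The generator emits a labelled dataset that mirrors the statistical
structure the pipeline is designed to detect: a shared synthetic
reference (the coordinate system), per-group substitution divergence and
length distributions, an assembly motif (SYGQ) planted with per-group
prevalence, and site-specific dipeptide states at fixed reference
coordinates (GC at 142/208/702 distinguishing vertebrates and
invertebrates, DH/EH at 41, FK/FL/FQ at 431 and KC/KF at 451
distinguishing vertebrate isoforms, plus one marker dipeptide per
non-vertebrate group).

So that planted dipeptide counts are *exact* class signals, every
dipeptide that appears in the site plan is scrubbed from the background:
stray occurrences outside planted sites are destroyed by substituting one
residue with proline (P), which participates in no planted dipeptide and
scores non-positively against every motif-template residue in BLOSUM62.
Stray motif windows (exact or one-similar-mismatch) are destroyed the
same way.  Indels never touch a planted site +/- 2 residues, so the
site-state truth stays well defined under alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .config import fork_seed
from .io import GROUPS, ISOFORMS, ProteinRecord
from .motif import _window_hit

#: UniProt-style average residue frequencies (fractions, sum to 1).
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0109, "Y": 0.0292, "V": 0.0687,
}
_TOTAL = sum(BACKGROUND_FREQS.values())
BACKGROUND_FREQS = {k: v / _TOTAL for k, v in BACKGROUND_FREQS.items()}


@dataclass(frozen=True)
class PlannedSite:
    """One reference coordinate with per-label dipeptide states.

    ``assign`` maps a group or isoform label to the state written there
    ("uniform" draws uniformly from ``states``); labels not in the map get
    a scrub-free background dipeptide instead.  ``canonical`` is the state
    written into the synthetic reference (None = background).
    """

    position: int  # 1-based position of the first residue
    canonical: Optional[str]
    assign: tuple[tuple[str, str], ...]
    states: tuple[str, ...]

    def state_for(self, group: str, isoform: Optional[str]) -> Optional[str]:
        table = dict(self.assign)
        if isoform is not None and isoform in table:
            return table[isoform]
        return table.get(group)


_UNI = "uniform"


def default_site_plan() -> tuple[PlannedSite, ...]:
    iso41 = (("a1", "EH"), ("a2", "EH"), ("a3", "DH"), ("a4", "EH"))
    iso431 = (("a1", "FK"), ("a2", "FL"), ("a3", "FK"), ("a4", "FQ"))
    iso451 = (("a1", "KC"), ("a2", "KF"), ("a3", "KF"), ("a4", "KF"))
    nonvert = tuple((g, _UNI) for g in GROUPS if g != "vertebrate")
    return (
        PlannedSite(41, "DH", iso41 + nonvert, ("DH", "EH")),
        PlannedSite(142, "GC", (("vertebrate", "GC"), ("invertebrate", "GC")), ("GC",)),
        PlannedSite(208, "GC", (("vertebrate", "GC"),), ("GC",)),
        PlannedSite(300, None, (("fungi", "HW"),), ("HW",)),
        PlannedSite(320, None, (("Protista", "WN"),), ("WN",)),
        PlannedSite(340, None, (("invertebrate", "WC"),), ("WC",)),
        PlannedSite(431, "FK", iso431 + nonvert, ("FK", "FL", "FQ")),
        PlannedSite(451, "KC", iso451 + nonvert, ("KC", "KF")),
        PlannedSite(702, "GC", (("vertebrate", "GC"), ("invertebrate", "GC")), ("GC",)),
    )


@dataclass
class SimConfig:
    """The stated world of the simulation.

    Defaults: 40 sequences per group (vertebrates split evenly over the
    four isoforms), prokaryote lengths 900 +/- 30 and 1020 +/- 20 for the
    other groups, motif prevalence 0 / 0.22 / 0.22 / 0.88 / 1.0 and
    substitution divergence from the reference decreasing from prokaryote
    (0.12) to vertebrate (0.03).
    """

    seed: int = 0
    n_per_group: dict = field(
        default_factory=lambda: {g: 40 for g in GROUPS}
    )
    reference_length: int = 1020
    length_distribution: dict = field(
        default_factory=lambda: {
            "prokaryote": (900.0, 30.0), "Protista": (1020.0, 20.0),
            "fungi": (1020.0, 20.0), "invertebrate": (1020.0, 20.0),
            "vertebrate": (1020.0, 20.0),
        }
    )
    background: dict = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    motif_prevalence: dict = field(
        default_factory=lambda: {
            "prokaryote": 0.0, "Protista": 0.22, "fungi": 0.22,
            "invertebrate": 0.88, "vertebrate": 1.0,
        }
    )
    motif_position: int = 860  # 1-based start of the planted SYGQ
    substitution_rate: dict = field(
        default_factory=lambda: {
            "prokaryote": 0.12, "Protista": 0.10, "fungi": 0.08,
            "invertebrate": 0.06, "vertebrate": 0.03,
        }
    )
    indel_rate: float = 0.005  # per-residue probability of an indel event
    site_plan: tuple[PlannedSite, ...] = field(default_factory=default_site_plan)

    def __post_init__(self) -> None:
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        for g, p in self.motif_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"motif prevalence for {g} outside [0, 1]")
        max_pos = max(s.position + 1 for s in self.site_plan)
        max_pos = max(max_pos, self.motif_position + 3)
        for g, (mu, _sd) in self.length_distribution.items():
            # short draws are clamped at generation time; the mean must
            # still clear the last planted coordinate
            if mu < max_pos + 1:
                raise ValueError(
                    f"{g}: mean length {mu} below the last site position {max_pos}"
                )
        # overlapping sites with conflicting letters are a configuration error
        letters: dict[int, str] = {}
        for site in self.site_plan:
            state = site.canonical
            for k in range(2):
                pos = site.position + k
                want = state[k] if state else None
                if pos in letters and want is not None and letters[pos] != want:
                    raise ValueError(
                        f"conflicting site states overlap at position {pos}"
                    )
                if want is not None:
                    letters[pos] = want

    def site_defs(self):
        """The planted sites as :class:`nkaminer.config.SiteDef` tuples."""
        from .config import SiteDef

        return tuple(SiteDef(s.position, s.states) for s in self.site_plan)

    @property
    def scrub_dipeptides(self) -> frozenset:
        out = set()
        for site in self.site_plan:
            out.update(site.states)
            if site.canonical:
                out.add(site.canonical)
        return frozenset(out)


@dataclass
class TruthRecord:
    """Planted facts for one emitted sequence, verifiable by rescanning."""

    id: str
    group: str
    isoform: Optional[str]
    motif_present: bool
    site_states: dict  # reference position -> written dipeptide state
    n_indels: int


# ---------------------------------------------------------------------------
# scrubbing helpers


def _scrub(seq: list[str], protected: set[int], scrub_pairs: frozenset,
           motif_start: Optional[int]) -> None:
    """Destroy stray scrub dipeptides and stray motif windows in place.

    ``protected`` holds 0-based indices that must not be edited (planted
    site residues and, for carriers, the motif window); ``motif_start`` is
    the 0-based start of a planted motif to keep, or None.
    """
    for _ in range(50):
        dirty = False
        for i in range(len(seq) - 1):
            pair = seq[i] + seq[i + 1]
            if pair not in scrub_pairs:
                continue
            if i in protected and i + 1 in protected:
                continue  # planted
            j = i + 1 if (i + 1) not in protected else i
            seq[j] = "P"
            dirty = True
        for i in range(len(seq) - 3):
            if motif_start is not None and i == motif_start:
                continue
            window = "".join(seq[i : i + 4])
            if _window_hit(window, "", i + 1) is None:
                continue
            free = [k for k in range(i, i + 4) if k not in protected]
            if not free:
                continue  # the planted window itself
            seq[free[-1]] = "P"
            dirty = True
        if not dirty:
            return
    raise RuntimeError("scrubbing did not converge")  # pragma: no cover


def _background_pair(rng: np.random.Generator, letters: np.ndarray,
                     probs: np.ndarray, scrub_pairs: frozenset) -> str:
    for _ in range(100):
        pair = "".join(rng.choice(letters, size=2, p=probs))
        if pair not in scrub_pairs:
            return pair
    raise RuntimeError("could not draw a scrub-free background pair")  # pragma: no cover


# ---------------------------------------------------------------------------
# generation


def simulate_reference(config: SimConfig) -> ProteinRecord:
    """Synthetic reference: background sequence with every canonical site
    state (and the SYGQ motif) written at its configured coordinate."""
    rng = np.random.default_rng(fork_seed(config.seed, "reference"))
    letters = np.array(sorted(config.background))
    probs = np.array([config.background[a] for a in letters])
    seq = list(rng.choice(letters, size=config.reference_length, p=probs))
    protected: set[int] = set()
    m0 = config.motif_position - 1
    seq[m0 : m0 + 4] = list("SYGQ")
    protected.update(range(m0, m0 + 4))
    for site in config.site_plan:
        p0 = site.position - 1
        state = site.canonical
        if state is None:
            pair = _background_pair(rng, letters, probs, config.scrub_dipeptides)
            seq[p0], seq[p0 + 1] = pair[0], pair[1]
        else:
            seq[p0], seq[p0 + 1] = state[0], state[1]
        protected.update((p0, p0 + 1))
    _scrub(seq, protected, config.scrub_dipeptides, m0)
    return ProteinRecord(id="synthetic_reference", sequence="".join(seq),
                         description="synthetic reference (coordinate system)")


def _forbidden_zone(protected: set[int], pad: int = 2) -> set[int]:
    out: set[int] = set()
    for p in protected:
        out.update(range(p - pad, p + pad + 1))
    return out


def _apply_indels(
    seq: list[str], protected: set[int], rng: np.random.Generator,
    letters: np.ndarray, probs: np.ndarray, target_length: int, indel_rate: float,
) -> tuple[list[str], set[int], int]:
    """Random small indels plus segment edits reaching the target length.

    Edits avoid ``protected`` +/- 2; returns the edited sequence, a map
    from original to shifted protected positions and the number of indel
    events.
    """
    n = len(seq)
    forbidden = _forbidden_zone(protected)
    edits: list[tuple[int, int, str]] = []  # (pos, del_len, inserted)
    used: set[int] = set()

    def claim(start: int, length: int) -> bool:
        span = set(range(start - 1, start + max(length, 1) + 1))
        if span & forbidden or span & used:
            return False
        used.update(span)
        return True

    k = int(rng.poisson(indel_rate * n))
    n_events = 0
    delta = 0
    for _ in range(k):
        length = int(rng.integers(1, 4))
        insert = bool(rng.integers(0, 2))
        for _try in range(50):
            pos = int(rng.integers(3, n - 3 - length))
            if claim(pos, 0 if insert else length):
                if insert:
                    ins = "".join(rng.choice(letters, size=length, p=probs))
                    edits.append((pos, 0, ins))
                    delta += length
                else:
                    edits.append((pos, length, ""))
                    delta -= length
                n_events += 1
                break
    # segment edits to land exactly on the target length
    need = target_length - (n + delta)
    while need != 0:
        length = min(abs(need), 40)
        for _try in range(200):
            pos = int(rng.integers(3, n - 3 - length))
            if claim(pos, 0 if need > 0 else length):
                if need > 0:
                    ins = "".join(rng.choice(letters, size=length, p=probs))
                    edits.append((pos, 0, ins))
                    need -= length
                else:
                    edits.append((pos, length, ""))
                    need += length
                n_events += 1
                break
        else:  # pragma: no cover - only under extreme configs
            raise RuntimeError("could not place length-adjusting indels")
    edits.sort(key=lambda e: -e[0])
    out = seq[:]
    for pos, dlen, ins in edits:
        out[pos : pos + dlen] = list(ins)
    shifted: dict[int, int] = {}
    for p in protected:
        shift = sum(
            (len(ins) - dlen) for pos, dlen, ins in edits if pos <= p
        )
        shifted[p] = p + shift
    return out, shifted, n_events


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[ProteinRecord], ProteinRecord, list[TruthRecord]]:
    """Emit (records, reference, truth) under the configured world."""
    reference = simulate_reference(config)
    rng = np.random.default_rng(fork_seed(config.seed, "dataset"))
    letters = np.array(sorted(config.background))
    probs = np.array([config.background[a] for a in letters])
    scrub = config.scrub_dipeptides
    m0 = config.motif_position - 1
    records: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        mu, sd = config.length_distribution[group]
        sub_rate = config.substitution_rate[group]
        prevalence = config.motif_prevalence[group]
        for i in range(n):
            isoform = ISOFORMS[i % 4] if group == "vertebrate" else None
            rid = f"{group[:4].lower()}_{i:03d}"
            seq = list(reference.sequence)
            # background divergence
            mask = rng.random(len(seq)) < sub_rate
            repl = rng.choice(letters, size=int(mask.sum()), p=probs)
            for j, r in zip(np.nonzero(mask)[0], repl):
                seq[j] = str(r)
            # planted site states
            protected: set[int] = set()
            site_states: dict[int, str] = {}
            for site in config.site_plan:
                p0 = site.position - 1
                state = site.state_for(group, isoform)
                if state == _UNI:
                    state = site.states[int(rng.integers(0, len(site.states)))]
                if state is None:
                    state = _background_pair(rng, letters, probs, scrub)
                seq[p0], seq[p0 + 1] = state[0], state[1]
                protected.update((p0, p0 + 1))
                site_states[site.position] = state
            # motif
            motif_present = bool(rng.random() < prevalence)
            if motif_present:
                seq[m0 : m0 + 4] = list("SYGQ")
                protected.update(range(m0, m0 + 4))
            _scrub(seq, protected, scrub, m0 if motif_present else None)
            # indels and length adjustment
            target = int(round(rng.normal(mu, sd)))
            target = max(target, max(protected) + 10)
            seq, shift_map, n_events = _apply_indels(
                seq, protected, rng, letters, probs, target, config.indel_rate
            )
            new_m0 = shift_map[m0] if motif_present else None
            _scrub(seq, set(shift_map.values()), scrub, new_m0)
            records.append(
                ProteinRecord(id=rid, sequence="".join(seq), group=group,
                              isoform=isoform)
            )
            truths.append(
                TruthRecord(id=rid, group=group, isoform=isoform,
                            motif_present=motif_present,
                            site_states=site_states, n_indels=n_events)
            )
    return records, reference, truths


def truth_to_json(truths: Sequence[TruthRecord], path) -> None:
    payload = [asdict(t) for t in truths]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def truth_from_json(path) -> list[TruthRecord]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        TruthRecord(
            id=d["id"], group=d["group"], isoform=d["isoform"],
            motif_present=d["motif_present"],
            site_states={int(k): v for k, v in d["site_states"].items()},
            n_indels=d["n_indels"],
        )
        for d in payload
    ]
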