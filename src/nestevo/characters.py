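"""Data model and I/O for the three avian nest characters.

A family is described by three set-valued characters: nest *structure*
(7 states), nest *site* (7 states) and nest *attachment* (4 states).
Families may carry several states per character (polymorphic families) or
none (brood parasites, mound builders, or families without data).  Two
dataset variants exist: "all" recorded states, and "effective" states —
those used by more than 10% of the (sub)sampled species of the family.

The on-disk format is a UTF-8 CSV with header
``family,passerine,missing_reason,structure,site,attachment``; multiple
states within a cell are separated by ``|``; an empty cell means no data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError, InvalidParameterError, VocabularyError

__all__ = [
    "CHARACTERS",
    "CharacterDefinition",
    "FamilyRecord",
    "CharacterMatrix",
    "read_character_matrix",
    "write_character_matrix",
    "derive_effective_states",
    "binary_recode",
    "state_frequencies",
    "RECODING_PRESETS",
    "N_BIRD_SPECIES",
    "N_BIRD_FAMILIES",
    "species_per_family",
]

#: global species/family counts used to justify the 50-species subsampling
#: cap (species per family averages ~45).
N_BIRD_SPECIES = 10_978
N_BIRD_FAMILIES = 242

MISSING_REASONS = ("none", "brood_parasite", "mound_builder", "no_data")


@dataclass(frozen=True)
class CharacterDefinition:
    name: str
    states: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise VocabularyError(f"{state!r} is not a {self.name} state") from None


CHARACTERS: dict[str, CharacterDefinition] = {
    "structure": CharacterDefinition(
        "structure",
        (
            "scrape",
            "platform",
            "cup",
            "simple dome",
            "dome with tunnel",
            "primary cavity",
            "secondary cavity",
        ),
    ),
    "site": CharacterDefinition(
        "site",
        (
            "ground",
            "tree",
            "non-tree vegetation",
            "cliff/bank",
            "underground",
            "water bodies",
            "termite/ant nests",
        ),
    ),
    "attachment": CharacterDefinition(
        "attachment",
        ("basal", "lateral", "horizontally forked", "pensile"),
    ),
}


@dataclass
class FamilyRecord:
    family: str
    states: dict[str, frozenset[str]] = field(default_factory=dict)
    missing_reason: str = "none"
    passerine: bool = False

    def __post_init__(self):
        if self.missing_reason not in MISSING_REASONS:
            raise VocabularyError(f"unknown missing_reason {self.missing_reason!r}")
        for char, ss in self.states.items():
            if char not in CHARACTERS:
                raise VocabularyError(f"unknown character {char!r}")
            for s in ss:
                CHARACTERS[char].index(s)
            self.states[char] = frozenset(ss)
        for char in CHARACTERS:
            self.states.setdefault(char, frozenset())
        has_states = any(self.states.get(c) for c in CHARACTERS)
        if self.missing_reason != "none" and has_states:
            raise VocabularyError(
                f"{self.family}: missing-data families must have empty state sets"
            )
        if self.missing_reason == "none" and not all(self.states.get(c) for c in CHARACTERS):
            raise VocabularyError(
                f"{self.family}: non-missing families need >= 1 state per character"
            )

    @property
    def is_missing(self) -> bool:
        return self.missing_reason != "none"


@dataclass
class CharacterMatrix:
    records: list[FamilyRecord]
    variant: str = "all"

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if r.family in seen:
                raise DuplicateRecordError(f"duplicate family {r.family!r}")
            seen.add(r.family)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.variant == other.variant
            and self.records == other.records
        )

    def get(self, family: str) -> FamilyRecord:
        for r in self.records:
            if r.family == family:
                return r
        raise KeyError(family)

    def families(self) -> list[str]:
        return [r.family for r in self.records]

    def subset(self, passerines_only: bool = False) -> "CharacterMatrix":
        recs = [r for r in self.records if r.passerine] if passerines_only else list(self.records)
        return CharacterMatrix(recs, variant=self.variant)

    def state_sets(self, character: str, as_indices: bool = True) -> dict:
        """Tip data for the Mk machinery: family -> set of state indices
        (or labels), None when the family is missing."""
        cd = CHARACTERS[character]
        out = {}
        for r in self.records:
            if r.is_missing:
                out[r.family] = None
            elif as_indices:
                out[r.family] = frozenset(cd.index(s) for s in r.states[character])
            else:
                out[r.family] = r.states[character]
        return out


def read_character_matrix(path, variant: str = "all") -> CharacterMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["family", "passerine", "missing_reason", "structure", "site", "attachment"]
    if list(df.columns) != expected:
        raise VocabularyError(f"bad header {list(df.columns)}; expected {expected}")
    records = []
    for row in df.itertuples(index=False):
        states = {}
        for char in CHARACTERS:
            cell = getattr(row, char).strip()
            states[char] = frozenset(s.strip() for s in cell.split("|")) if cell else frozenset()
        records.append(
            FamilyRecord(
                family=row.family,
                states=states,
                missing_reason=row.missing_reason or "none",
                passerine=row.passerine in ("1", "true", "True"),
            )
        )
    return CharacterMatrix(records, variant=variant)


def write_character_matrix(matrix: CharacterMatrix, path) -> None:
    rows = []
    for r in matrix.records:
        row = {
            "family": r.family,
            "passerine": int(r.passerine),
            "missing_reason": r.missing_reason,
        }
        for char in CHARACTERS:
            ss = r.states.get(char, frozenset())
            order = CHARACTERS[char].states
            row[char] = "|".join(sorted(ss, key=order.index))
        rows.append(row)
    cols = ["family", "passerine", "missing_reason", "structure", "site", "attachment"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def species_per_family(n_species: int = N_BIRD_SPECIES, n_families: int = N_BIRD_FAMILIES) -> int:
    """Mean species per family, rounded — the rationale for capping the
    per-family species subsample at 50 (10,978 / 242 ~ 45)."""
    return round(n_species / n_families)


def derive_effective_states(
    species_table: dict[str, tuple[str, frozenset[str] | set[str]]],
    threshold: float = 0.10,
    cap: int = 50,
    seed=0,
) -> frozenset[str]:
    """States used by strictly more than ``threshold`` of a family's species.

    ``species_table`` maps species -> (genus, state set).  Families with at
    most ``cap`` species with data use all of them; larger families are
    subsampled to ``cap`` species approximately evenly across genera
    (seeded round-robin over lexicographically sorted genera, species order
    shuffled within each genus).
    """
    if not 0 < threshold < 1:
        raise InvalidParameterError("threshold must lie in (0, 1)")
    species = {sp: gs for sp, gs in species_table.items() if gs[1]}
    if not species:
        warnings.warn("empty species table; no effective states", UserWarning)
        return frozenset()
    if len(species) <= cap:
        chosen = list(species)
    else:
        rng = np.random.default_rng(seed)
        by_genus: dict[str, list[str]] = {}
        for sp in sorted(species):
            by_genus.setdefault(species[sp][0], []).append(sp)
        queues = []
        for genus in sorted(by_genus):
            sps = by_genus[genus]
            rng.shuffle(sps)
            queues.append(sps)
        chosen = []
        round_idx = 0
        while len(chosen) < cap:
            advanced = False
            for q in queues:
                if round_idx < len(q):
                    chosen.append(q[round_idx])
                    advanced = True
                    if len(chosen) == cap:
                        break
            round_idx += 1
            if not advanced:
                break
    n = len(chosen)
    counts: dict[str, int] = {}
    for sp in chosen:
        for s in species[sp][1]:
            counts[s] = counts.get(s, 0) + 1
    return frozenset(s for s, c in counts.items() if c / n > threshold)


def binary_recode(
    matrix: CharacterMatrix,
    character: str,
    focal_states,
    derived_label: str,
    ancestral_label: str,
) -> dict[str, str | None]:
    """Collapse a multi-state character to a binary one.

    ``focal_states`` define the ancestral category: a family whose state
    set intersects the complement of ``focal_states`` is coded with
    ``derived_label`` (families carrying states of both categories are
    assigned the later-derived state), families entirely within
    ``focal_states`` get ``ancestral_label``, and missing families stay
    missing (None).
    """
    focal = frozenset(focal_states)
    if not focal:
        raise InvalidParameterError("focal_states must be non-empty")
    cd = CHARACTERS[character]
    for s in focal:
        cd.index(s)
    out: dict[str, str | None] = {}
    for r in matrix.records:
        if r.is_missing:
            out[r.family] = None
        elif r.states[character] - focal:
            out[r.family] = derived_label
        else:
            out[r.family] = ancestral_label
    return out


#: the three coevolution case studies: (character, focal/ancestral states,
#: derived label, ancestral label) for each member of the pair.
RECODING_PRESETS: dict[str, tuple] = {
    "scrape_x_ground": (
        ("structure", {"scrape"}, "non-scrape", "scrape"),
        ("site", {"ground"}, "non-ground", "ground"),
    ),
    "cup_x_nontree_vegetation": (
        ("structure", set(CHARACTERS["structure"].states) - {"cup"}, "cup", "non-cup"),
        (
            "site",
            set(CHARACTERS["site"].states) - {"non-tree vegetation"},
            "non-tree vegetation",
            "other site",
        ),
    ),
    "cup_dome_x_nonbasal": (
        (
            "structure",
            {"scrape", "platform", "primary cavity", "secondary cavity"},
            "cup/dome",
            "other structure",
        ),
        ("attachment", {"basal"}, "non-basal", "basal"),
    ),
}


def apply_recoding_preset(matrix: CharacterMatrix, preset: str) -> tuple[dict, dict]:
    """Binary trait maps (A, B) for one of the named coevolution cases.
    The derived label is always coded 1 downstream."""
    spec_a, spec_b = RECODING_PRESETS[preset]
    return (
        binary_recode(matrix, spec_a[0], spec_a[1], spec_a[2], spec_a[3]),
        binary_recode(matrix, spec_b[0], spec_b[1], spec_b[2], spec_b[3]),
    )


def state_frequencies(
    matrix: CharacterMatrix, character: str, denominator: str = "with_data"
) -> pd.DataFrame:
    """Exclusive and inclusive per-state counts and proportions.

    Exclusive: the family's state set is exactly {state}; inclusive: the
    set contains the state.  Proportions are over families with data for
    the character (``denominator='with_data'``) or over all families
    (``denominator='all'``).
    """
    cd = CHARACTERS[character]
    with_data = [r for r in matrix.records if not r.is_missing]
    if not with_data:
        warnings.warn(f"no families with data for {character}", UserWarning)
        return pd.DataFrame(
            columns=["n_exclusive", "n_inclusive", "p_exclusive", "p_inclusive"]
        )
    denom = len(matrix.records) if denominator == "all" else len(with_data)
    rows = {}
    for s in cd.states:
        n_ex = sum(1 for r in with_data if r.states[character] == {s})
        n_in = sum(1 for r in with_data if s in r.states[character])
        rows[s] = {
            "n_exclusive": n_ex,
            "n_inclusive": n_in,
            "p_exclusive": n_ex / denom,
            "p_inclusive": n_in / denom,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["n_with_data"] = len(with_data)
    df.attrs["denominator"] = denom
    return df
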