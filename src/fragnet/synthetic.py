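"""Synthetic scaffold-family SMILES corpora for desk-scale experiments.

Members of one family share a ring scaffold and differ by substituents,
so within-family structural (Tanimoto) similarity exceeds the
between-family similarity — the premise the contrastive-recovery tests
rely on.  Scaffolds carry at least six heavy atoms and substitution
breaks their symmetry, so SMILES enumeration yields genuinely distinct
positive-pair strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .smiles_data import MoleculeRecord, SmilesParseError, canonicalize

PLACEHOLDER = "{R}"

DEFAULT_SUBSTITUENTS = [
    "C", "CC", "CCC", "O", "N", "CO", "CCO", "C(C)C",
    "Cl", "Br", "C(=O)C", "OC",
]

# wider pool for corpora larger than the default 3 x 8 fixture
EXTENDED_SUBSTITUENTS = DEFAULT_SUBSTITUENTS + [
    "F", "CN", "C#N", "CCN", "C(=O)O", "C(=O)N", "OCC", "CCCC",
    "C(C)(C)C", "CBr", "CCl", "N(C)C",
]


@dataclass(frozen=True)
class FamilySpec:
    """A scaffold with one substitution point plus candidate substituents."""

    name: str
    scaffold: str               # SMILES containing the {R} placeholder
    substituents: list[str]
    n_members: int
    label: str


DEFAULT_FAMILY_SPECS = [
    FamilySpec("benzene", "c1ccc({R})cc1", DEFAULT_SUBSTITUENTS, 8, "drug"),
    FamilySpec("cyclohexane", "C1CCC({R})CC1", DEFAULT_SUBSTITUENTS, 8,
               "metabolite"),
    FamilySpec("pyridine", "c1ccnc({R})c1", DEFAULT_SUBSTITUENTS, 8,
               "natural_product"),
]

# short, low-symmetry molecules for quick memorization experiments
TINY_SMILES = ["CCO", "CC(=O)O", "c1ccccc1", "CC(C)O", "CCN"]


def generate_families(specs: list[FamilySpec],
                      rng: np.random.Generator) -> list[MoleculeRecord]:
    """Instantiate each scaffold with sampled substituent choices.

    Substituents are drawn without replacement per family, so members
    are distinct; every generated SMILES is validated and stored in
    canonical form.  Deterministic under the rng seed.
    """
    if not specs:
        raise ValueError("no family specs given")
    records: list[MoleculeRecord] = []
    for spec in specs:
        if PLACEHOLDER not in spec.scaffold:
            raise ValueError(
                f"scaffold {spec.scaffold!r} lacks the {PLACEHOLDER} site")
        if spec.n_members > len(spec.substituents):
            raise ValueError(
                f"family {spec.name}: {spec.n_members} members requested "
                f"but only {len(spec.substituents)} substituents")
        chosen = rng.choice(len(spec.substituents), size=spec.n_members,
                            replace=False)
        for j, ci in enumerate(chosen):
            smiles = spec.scaffold.replace(PLACEHOLDER,
                                           spec.substituents[int(ci)])
            try:
                canonical = canonicalize(smiles)
            except SmilesParseError as exc:
                raise ValueError(
                    f"family {spec.name}: invalid member {smiles!r}") from exc
            records.append(MoleculeRecord(
                id=f"{spec.name}_{j}", canonical_smiles=canonical,
                label=spec.label))
    return records


def default_fixture(size: str = "small") -> list[MoleculeRecord]:
    """Frozen corpora: 'tiny' = 5 short molecules, 'small' = 3 families x 8."""
    if size == "tiny":
        return [MoleculeRecord(id=f"tiny_{i}", canonical_smiles=canonicalize(s),
                               label="other")
                for i, s in enumerate(TINY_SMILES)]
    if size == "small":
        return generate_families(DEFAULT_FAMILY_SPECS,
                                 np.random.default_rng(20250928))
    raise ValueError(f"unknown fixture size {size!r}")
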