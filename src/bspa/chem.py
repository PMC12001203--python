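"""Reaction-array enumeration with explicit mass/adduct bookkeeping.

A campaign iteration is a :class:`Route`: an ordered list of stages, each
applying one :class:`ReactionStep` (a reaction-SMARTS rule, configuration
data rather than code) to the running intermediate and one or more building
block sets.  Enumerating a route yields one :class:`ProductTarget` per
applicable block combination, carrying the Hill formula, monoisotopic and
average masses, and the expected ion m/z for each configured adduct — the
quantities the LCMS quality-control layer searches for.

Chemistry correctness beyond mass bookkeeping is deliberately not validated:
the enumerator checks that each step's mass balance closes (product mass =
sum of input masses minus the leaving group) but does not judge whether a
reaction would actually proceed.
"""

from __future__ import annotations

import csv
import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .constants import ISOTOPE_MASSES, PROTON_MASS

RDLogger.DisableLog("rdApp.*")

MASS_CLOSURE_TOL = 1e-6

__all__ = [
    "AdductRule",
    "BuildingBlock",
    "ChemParseError",
    "EnumerationResult",
    "ProductTarget",
    "ReactionStep",
    "Route",
    "RouteError",
    "Stage",
    "STANDARD_ADDUCTS",
    "compute_formula_mass",
    "enumerate_products",
    "expected_ion_mz",
    "load_blocks_csv",
    "load_route_yaml",
    "write_targets_csv",
    "load_targets_csv",
]


class ChemParseError(ValueError):
    """A structure or formula string could not be parsed."""


class RouteError(ValueError):
    """A route is malformed or cannot be satisfied from the given blocks."""


@dataclass(frozen=True)
class AdductRule:
    """Ionization adduct: m/z = (M + delta_mass) / |charge|."""

    name: str
    delta_mass: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"adduct {self.name!r}: charge must be non-zero")

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.delta_mass) / abs(self.charge)


STANDARD_ADDUCTS: dict[str, AdductRule] = {
    "[M+H]+": AdductRule("[M+H]+", PROTON_MASS, +1),
    "[M+Na]+": AdductRule("[M+Na]+", 22.989218, +1),
    "[M+2H]2+": AdductRule("[M+2H]2+", 2 * PROTON_MASS, +2),
    "[M-H]-": AdductRule("[M-H]-", -PROTON_MASS, -1),
}


@dataclass(frozen=True)
class BuildingBlock:
    """One array input: an identified structure with a reactivity role."""

    id: str
    smiles: str
    role: str
    iteration: str = ""

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ChemParseError(f"building block {self.id!r}: cannot parse SMILES {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class ReactionStep:
    """One transformation rule of a route.

    ``rule`` is reaction SMARTS whose reactant order matches ``input_roles``.
    ``leaving_formula`` is the molecular formula removed by the step (empty
    string when the step is a pure addition); it is used only for the mass
    closure check.
    """

    id: str
    rule: str
    input_roles: tuple[str, ...]
    leaving_formula: str = ""

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.rule)
        if rxn is None:
            raise ChemParseError(f"step {self.id!r}: cannot parse reaction SMARTS")
        if rxn.GetNumReactantTemplates() != len(self.input_roles):
            raise RouteError(
                f"step {self.id!r}: {rxn.GetNumReactantTemplates()} reactant templates "
                f"but {len(self.input_roles)} input roles"
            )
        return rxn


@dataclass(frozen=True)
class Stage:
    """A route stage: the step plus, for each role, which block list feeds it.

    The reserved role name ``product`` refers to the output of the previous
    stage (or, inside a merge stage, to a branch output named
    ``product:<branch id>``).
    """

    step: ReactionStep
    inputs: tuple[str, ...]  # one entry per step input role: block-list key or "product[:branch]"


@dataclass(frozen=True)
class Route:
    """An ordered multi-step synthesis plan, optionally with parallel branches
    whose products are combined by the final merge stage."""

    id: str
    stages: tuple[Stage, ...] = ()
    branches: tuple["Route", ...] = ()
    merge: Stage | None = None

    def __post_init__(self) -> None:
        if self.branches and self.merge is None:
            raise RouteError(f"route {self.id!r}: branches require a merge stage")
        if not self.branches and not self.stages:
            raise RouteError(f"route {self.id!r}: no stages")


@dataclass(frozen=True)
class ProductTarget:
    """An enumerated expected product and its expected ions."""

    id: str
    smiles: str
    formula: str
    mono_mass: float
    avg_mass: float
    expected_ions: tuple[tuple[str, float, int], ...]  # (adduct name, m/z, charge)
    provenance: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class EnumerationResult:
    """Products plus per-combination failures (enumeration always continues)."""

    targets: list[ProductTarget]
    skipped: list[tuple[tuple[str, ...], str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# formulas and masses

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Counter:
    """Molecular formula string -> element counts."""
    counts: Counter = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ChemParseError(f"cannot parse formula {formula!r}")
        element, digits = match.groups()
        if element not in ISOTOPE_MASSES:
            raise ChemParseError(f"formula {formula!r}: unknown element {element!r}")
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise ChemParseError(f"cannot parse formula {formula!r}")
    return counts


def formula_masses(counts: Mapping[str, int]) -> tuple[float, float]:
    """(monoisotopic, average) mass of an element-count mapping."""
    mono = sum(n * ISOTOPE_MASSES[el][0] for el, n in counts.items())
    avg = sum(n * ISOTOPE_MASSES[el][1] for el, n in counts.items())
    return mono, avg


def _hill_formula(counts: Mapping[str, int]) -> str:
    """Hill order: C first, then H, then other elements alphabetically."""

    def fmt(el: str) -> str:
        n = counts[el]
        return f"{el}{n if n > 1 else ''}" if n else ""

    elements = sorted(el for el in counts if counts[el])
    if counts.get("C"):
        ordered = ["C"] + (["H"] if counts.get("H") else [])
        ordered += [el for el in elements if el not in ("C", "H")]
    else:
        ordered = elements
    return "".join(fmt(el) for el in ordered)


def _mol_element_counts(mol: Chem.Mol) -> Counter:
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in ISOTOPE_MASSES:
            raise ChemParseError(f"unsupported element {symbol!r} in {Chem.MolToSmiles(mol)!r}")
        counts[symbol] += 1
        counts["H"] += atom.GetTotalNumHs()
    return counts


def compute_formula_mass(smiles: str) -> tuple[str, float, float]:
    """Hill formula, monoisotopic mass and average mass of a structure.

    The monoisotopic mass is the sum of most-abundant-isotope masses over the
    internal table; charge states and explicit isotopes are not handled.
    """
    if not smiles:
        raise ChemParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemParseError(f"cannot parse SMILES {smiles!r}")
    counts = _mol_element_counts(mol)
    mono, avg = formula_masses(counts)
    return _hill_formula(counts), mono, avg


def expected_ion_mz(mono_mass: float, adduct: AdductRule) -> float:
    """Expected m/z of an adduct ion of a neutral molecule of mass ``mono_mass``."""
    if mono_mass <= 0:
        raise ValueError(f"mono_mass must be positive, got {mono_mass}")
    return adduct.mz(mono_mass)


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemParseError(f"cannot parse SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# enumeration

def _strip_stereo_smiles(mol: Chem.Mol) -> str:
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def _enantiomer_smiles(mol: Chem.Mol, cap: int = 4) -> tuple[str, ...]:
    """Isomeric SMILES of the stereoisomers of unassigned centres (racemic
    building blocks yield racemic products; both forms share one target)."""
    opts = StereoEnumerationOptions(maxIsomers=cap, onlyUnassigned=True, unique=True)
    try:
        isomers = list(EnumerateStereoisomers(mol, options=opts))
    except Exception:
        return ()
    if len(isomers) <= 1:
        return ()
    return tuple(sorted(Chem.MolToSmiles(m) for m in isomers))


def _run_step(step: ReactionStep, reactants: Sequence[Chem.Mol]) -> Chem.Mol | None:
    rxn = step.reaction()
    products = rxn.RunReactants(tuple(reactants))
    if not products:
        return None
    mol = products[0][0]
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


@dataclass(frozen=True)
class _Intermediate:
    mol: Chem.Mol
    block_ids: tuple[str, ...]
    step_ids: tuple[str, ...]
    input_mono: float  # running sum of block monoisotopic masses
    leaving_mono: float  # running sum of leaving-group monoisotopic masses


def _enumerate_linear(
    route_id: str,
    stages: Sequence[Stage],
    blocks: Mapping[str, Sequence[BuildingBlock]],
    seeds: Sequence[_Intermediate],
    skipped: list[tuple[tuple[str, ...], str]],
) -> list[_Intermediate]:
    current = list(seeds)
    for stage in stages:
        step = stage.step
        block_slots: list[list[BuildingBlock]] = []
        for role, source in zip(step.input_roles, stage.inputs):
            if source.startswith("product"):
                block_slots.append([])  # filled from the running intermediate
                continue
            pool = blocks.get(source, ())
            if not pool:
                raise RouteError(
                    f"route {route_id!r} step {step.id!r}: no building blocks for "
                    f"role {role!r} (block list {source!r})"
                )
            block_slots.append(sorted(pool, key=lambda b: b.id))
        leaving_mono = (
            formula_masses(parse_formula(step.leaving_formula))[0]
            if step.leaving_formula
            else 0.0
        )
        nxt: list[_Intermediate] = []
        for inter in current:
            combos = itertools.product(
                *[slot if slot else [None] for slot in block_slots]
            )
            for combo in combos:
                reactants: list[Chem.Mol] = []
                combo_ids = inter.block_ids
                block_mono = 0.0
                bad: str | None = None
                for source, block in zip(stage.inputs, combo):
                    if block is None:
                        reactants.append(inter.mol)
                        continue
                    try:
                        mol = block.mol()
                    except ChemParseError as exc:
                        bad = str(exc)
                        break
                    reactants.append(mol)
                    combo_ids = combo_ids + (block.id,)
                    block_mono += formula_masses(_mol_element_counts(mol))[0]
                if bad is not None:
                    skipped.append((combo_ids, bad))
                    continue
                product = _run_step(step, reactants)
                if product is None:
                    skipped.append(
                        (combo_ids, f"step {step.id!r}: rule not applicable")
                    )
                    continue
                nxt.append(
                    _Intermediate(
                        mol=product,
                        block_ids=combo_ids,
                        step_ids=inter.step_ids + (step.id,),
                        input_mono=inter.input_mono + block_mono,
                        leaving_mono=inter.leaving_mono + leaving_mono,
                    )
                )
        current = nxt
    return current


def enumerate_products(
    route: Route,
    blocks: Mapping[str, Sequence[BuildingBlock]],
    adducts: Iterable[AdductRule] = (STANDARD_ADDUCTS["[M+H]+"],),
    check_mass_closure: bool = True,
) -> EnumerationResult:
    """Enumerate a route into expected products.

    Combinations are visited in lexicographic order of block ids, so the
    output table is deterministic.  Unapplicable or unparseable combinations
    are recorded in ``skipped`` and enumeration continues; an unsatisfiable
    role aborts with :class:`RouteError`.
    """
    adducts = tuple(adducts)
    skipped: list[tuple[tuple[str, ...], str]] = []
    empty_seed = _Intermediate(Chem.Mol(), (), (), 0.0, 0.0)

    if route.branches:
        branch_products: list[list[_Intermediate]] = []
        for branch in route.branches:
            branch_products.append(
                _enumerate_linear(branch.id, branch.stages, blocks, [empty_seed], skipped)
            )
        assert route.merge is not None
        merged: list[_Intermediate] = []
        step = route.merge.step
        branch_index = {f"product:{b.id}": i for i, b in enumerate(route.branches)}
        try:
            reactant_order = [branch_index[src] for src in route.merge.inputs]
        except KeyError as exc:
            raise RouteError(
                f"route {route.id!r}: merge input {exc.args[0]!r} does not name a branch"
            ) from None
        leaving_mono = (
            formula_masses(parse_formula(step.leaving_formula))[0]
            if step.leaving_formula
            else 0.0
        )
        for combo in itertools.product(*branch_products):
            product = _run_step(step, [combo[i].mol for i in reactant_order])
            ids = tuple(itertools.chain.from_iterable(i.block_ids for i in combo))
            if product is None:
                skipped.append((ids, f"merge step {step.id!r}: rule not applicable"))
                continue
            merged.append(
                _Intermediate(
                    mol=product,
                    block_ids=ids,
                    step_ids=tuple(
                        itertools.chain.from_iterable(i.step_ids for i in combo)
                    )
                    + (step.id,),
                    input_mono=sum(i.input_mono for i in combo),
                    leaving_mono=sum(i.leaving_mono for i in combo) + leaving_mono,
                )
            )
        finals = merged
    else:
        finals = _enumerate_linear(route.id, route.stages, blocks, [empty_seed], skipped)

    targets: list[ProductTarget] = []
    seen: dict[str, int] = {}
    for inter in finals:
        smiles = _strip_stereo_smiles(inter.mol)
        counts = _mol_element_counts(inter.mol)
        mono, avg = formula_masses(counts)
        if check_mass_closure and abs(mono - (inter.input_mono - inter.leaving_mono)) > MASS_CLOSURE_TOL:
            skipped.append(
                (
                    inter.block_ids,
                    f"mass closure violated: product {mono:.6f} Da vs "
                    f"inputs-leaving {inter.input_mono - inter.leaving_mono:.6f} Da",
                )
            )
            continue
        if smiles in seen:
            # racemic collapse: same flat structure, keep one target
            prior = targets[seen[smiles]]
            enantiomers = tuple(
                sorted(set(prior.provenance.get("enantiomers", ()))
                       | {Chem.MolToSmiles(inter.mol)})
            )
            targets[seen[smiles]] = ProductTarget(
                id=prior.id,
                smiles=prior.smiles,
                formula=prior.formula,
                mono_mass=prior.mono_mass,
                avg_mass=prior.avg_mass,
                expected_ions=prior.expected_ions,
                provenance={**prior.provenance, "enantiomers": enantiomers},
            )
            continue
        ions = tuple(
            (adduct.name, expected_ion_mz(mono, adduct), adduct.charge)
            for adduct in adducts
        )
        provenance: dict[str, tuple[str, ...]] = {
            "blocks": inter.block_ids,
            "steps": inter.step_ids,
        }
        enantiomers = _enantiomer_smiles(inter.mol)
        if enantiomers:
            provenance["enantiomers"] = enantiomers
        seen[smiles] = len(targets)
        targets.append(
            ProductTarget(
                id=f"{route.id}-" + "_".join(inter.block_ids),
                smiles=smiles,
                formula=_hill_formula(counts),
                mono_mass=mono,
                avg_mass=avg,
                expected_ions=ions,
                provenance=provenance,
            )
        )
    return EnumerationResult(targets=targets, skipped=skipped)


# ---------------------------------------------------------------------------
# I/O

def load_blocks_csv(path: str | Path) -> dict[str, list[BuildingBlock]]:
    """Read building blocks (id, smiles, role, iteration) grouped by role."""
    by_role: dict[str, list[BuildingBlock]] = {}
    ids: set[str] = set()
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            block = BuildingBlock(
                id=row["id"],
                smiles=row["smiles"],
                role=row["role"],
                iteration=row.get("iteration", ""),
            )
            if block.id in ids:
                raise ValueError(f"duplicate building block id {block.id!r}")
            ids.add(block.id)
            by_role.setdefault(block.role, []).append(block)
    return by_role


def load_blocks_sdf(path: str | Path, role_prop: str = "role",
                    iteration_prop: str = "iteration") -> dict[str, list[BuildingBlock]]:
    """Read building blocks from an SDF, grouped by the role property.

    Each record needs a title (or ``id`` property) and a ``role`` property;
    the iteration tag is optional.
    """
    by_role: dict[str, list[BuildingBlock]] = {}
    ids: set[str] = set()
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            raise ChemParseError(f"{path}: cannot parse SDF record {i}")
        props = mol.GetPropsAsDict()
        block_id = props.get("id") or mol.GetProp("_Name") or f"record-{i}"
        if block_id in ids:
            raise ValueError(f"duplicate building block id {block_id!r}")
        ids.add(block_id)
        block = BuildingBlock(
            id=str(block_id),
            smiles=Chem.MolToSmiles(mol),
            role=str(props.get(role_prop, "")),
            iteration=str(props.get(iteration_prop, "")),
        )
        by_role.setdefault(block.role, []).append(block)
    return by_role


def _parse_stage(raw: Mapping, steps: Mapping[str, ReactionStep]) -> Stage:
    step = steps[raw["step"]]
    inputs = tuple(raw["inputs"][role] for role in step.input_roles)
    return Stage(step=step, inputs=inputs)


def load_route_yaml(path: str | Path) -> tuple[Route, tuple[AdductRule, ...]]:
    """Read a route config: reaction steps, stages/branches and adduct list."""
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    steps = {
        raw["id"]: ReactionStep(
            id=raw["id"],
            rule=raw["rule"],
            input_roles=tuple(raw["input_roles"]),
            leaving_formula=raw.get("leaving_formula", "") or "",
        )
        for raw in doc.get("steps", [])
    }
    adducts = tuple(
        AdductRule(raw["name"], float(raw["delta_mass"]), int(raw["charge"]))
        if isinstance(raw, Mapping)
        else STANDARD_ADDUCTS[raw]
        for raw in doc.get("adducts", ["[M+H]+"])
    )
    branches = tuple(
        Route(
            id=braw["id"],
            stages=tuple(_parse_stage(s, steps) for s in braw["stages"]),
        )
        for braw in doc.get("branches", [])
    )
    route = Route(
        id=doc["id"],
        stages=tuple(_parse_stage(s, steps) for s in doc.get("stages", [])),
        branches=branches,
        merge=_parse_stage(doc["merge"], steps) if "merge" in doc else None,
    )
    return route, adducts


def write_targets_csv(targets: Iterable[ProductTarget], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "smiles", "formula", "mono_mass", "avg_mass", "expected_ions"])
        for t in targets:
            ions = ";".join(f"{name}:{mz:.6f}:{z}" for name, mz, z in t.expected_ions)
            writer.writerow([t.id, t.smiles, t.formula, f"{t.mono_mass:.6f}", f"{t.avg_mass:.6f}", ions])


def load_targets_csv(path: str | Path) -> list[ProductTarget]:
    targets = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            ions = tuple(
                (name, float(mz), int(z))
                for name, mz, z in (item.split(":") for item in row["expected_ions"].split(";") if item)
            )
            targets.append(
                ProductTarget(
                    id=row["id"],
                    smiles=row["smiles"],
                    formula=row["formula"],
                    mono_mass=float(row["mono_mass"]),
                    avg_mass=float(row["avg_mass"]),
                    expected_ions=ions,
                )
            )
    return targets
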