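"""Example campaign configurations: six iterations of growing complexity.

Routes ship as YAML configs (reaction rules are configuration data, not
code); building-block lists are generated programmatically as simple
homologous series so that example campaigns of realistic size need no large
data files.  Target counts per iteration: 58, 58, 64, 512, 1024 and 160
(the last combining two parallel two-step branches).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from ..chem import (
    AdductRule,
    BuildingBlock,
    EnumerationResult,
    Route,
    enumerate_products,
    load_route_yaml,
)

__all__ = [
    "ITERATIONS",
    "enumerate_iteration",
    "iteration_blocks",
    "load_example_route",
    "write_blocks_csv",
]

ITERATIONS = ("iter1", "iter1_1", "iter2", "iter3", "iter3_5", "iter4_2")

# small curated heads; homologous alkyl series pad each list to size
_ARYL = ["c1ccccc1", "c1ccc(C)cc1", "c1ccc(Cl)cc1", "c1ccc(F)cc1", "c1ccc(OC)cc1"]


def _alkyl(k: int) -> str:
    return "C" * (k + 1)


def _series(n: int, prefix: str, suffix: str, heads: list[str] | None = None) -> list[str]:
    """``n`` distinct SMILES: curated heads then linear homologs."""
    out = list(heads or [])[:n]
    k = 0
    while len(out) < n:
        out.append(prefix + _alkyl(k) + suffix)
        k += 1
    return out


def _blocks(role: str, smiles: list[str], iteration: str) -> list[BuildingBlock]:
    width = len(str(len(smiles)))
    return [
        BuildingBlock(id=f"{iteration}-{role}-{i:0{width}d}", smiles=s,
                      role=role, iteration=iteration)
        for i, s in enumerate(smiles, start=1)
    ]


def iteration_blocks(iteration: str) -> dict[str, list[BuildingBlock]]:
    """Building-block lists (by block-list name) for an example iteration."""
    if iteration == "iter1":
        return {
            "core_amine": _blocks("core_amine", ["O=C(c1ccco1)N1CCNCC1"], iteration),
            "isocyanate": _blocks(
                "isocyanate",
                _series(58, "", "N=C=O", [f"O=C=N{a}" for a in _ARYL]),
                iteration),
        }
    if iteration == "iter1_1":
        return {
            "core_amine": _blocks("core_amine", ["CC(C)C(=O)N1CCNCC1"], iteration),
            "isocyanate": _blocks(
                "isocyanate",
                _series(58, "", "N=C=O", [f"O=C=N{a}" for a in _ARYL]),
                iteration),
        }
    if iteration == "iter2":
        return {
            "core_amine": _blocks("core_amine", ["O=C(NC1CC1)N1CCNCC1"], iteration),
            "acid": _blocks(
                "acid",
                _series(64, "", "C(=O)O",
                        ["OC(=O)c1ccco1", "OC(=O)c1cccs1"] +
                        [f"OC(=O){a}" for a in _ARYL]),
                iteration),
        }
    if iteration == "iter3":
        return {
            "core_diamine": _blocks("core_diamine", ["CC1CNCCN1"], iteration),
            "acid": _blocks("acid", _series(64, "", "C(=O)O", ["OC(=O)c1ccco1"]), iteration),
            "aldehyde": _blocks("aldehyde", _series(8, "", "C=O", ["O=Cc1ccco1"]), iteration),
        }
    if iteration == "iter3_5":
        return {
            "core_diamine": _blocks("core_diamine", ["CC1CNCCN1"], iteration),
            "acid": _blocks("acid", _series(16, "", "C(=O)O", ["OC(=O)c1ccco1"]), iteration),
            "isocyanate": _blocks("isocyanate", _series(64, "", "N=C=O",
                                                        [f"O=C=N{a}" for a in _ARYL]),
                                  iteration),
        }
    if iteration == "iter4_2":
        return {
            "amino_alcohol": _blocks("amino_alcohol",
                                     [f"OC{_alkyl(k)}N" for k in range(4)], iteration),
            "aldehyde_a": _blocks("aldehyde_a", _series(2, "", "C=O"), iteration),
            "cap_acid": _blocks("cap_acid", _series(1, "", "C(=O)O"), iteration),
            "amino_acid": _blocks("amino_acid",
                                  [f"NC{_alkyl(k)}C(=O)O" for k in range(5)], iteration),
            "aldehyde_b": _blocks("aldehyde_b", _series(2, "", "C=O"), iteration),
            "isocyanate_b": _blocks("isocyanate_b", _series(2, "", "N=C=O"), iteration),
        }
    raise KeyError(f"unknown example iteration {iteration!r}; choose from {ITERATIONS}")


def load_example_route(iteration: str) -> tuple[Route, tuple[AdductRule, ...]]:
    if iteration not in ITERATIONS:
        raise KeyError(f"unknown example iteration {iteration!r}; choose from {ITERATIONS}")
    ref = resources.files(__package__) / "routes" / f"{iteration}.yaml"
    with resources.as_file(ref) as path:
        return load_route_yaml(path)


def enumerate_iteration(iteration: str) -> EnumerationResult:
    """Enumerate one example iteration into product targets."""
    route, adducts = load_example_route(iteration)
    return enumerate_products(route, iteration_blocks(iteration), adducts=adducts)


def write_blocks_csv(iteration: str, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["id", "smiles", "role", "iteration"])
        for blocks in iteration_blocks(iteration).values():
            for b in blocks:
                writer.writerow([b.id, b.smiles, b.role, b.iteration])
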