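"""Shared fixtures: hand-built PDB text and session-scoped toy structures."""

from __future__ import annotations

import numpy as np
import pytest


def pdb_line(serial, name, res_name, chain, res_id, x, y, z,
             occ=1.0, altloc=" ", hetero=False, element="C"):
    """One fixed-column ATOM/HETATM record."""
    record = "HETATM" if hetero else "ATOM"
    name_field = f" {name:<3}" if len(name) < 4 else name[:4]
    return (f"{record:<6}{serial:>5} {name_field}{altloc}{res_name:<3} "
            f"{chain}{res_id:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def make_pdb(lines):
    return "\n".join(lines + ["END"]) + "\n"


def protein_residue(serial0, res_id, chain="A", offset=(0.0, 0.0, 0.0)):
    """A minimal alanine: N, CA, C, O backbone records."""
    ox, oy, oz = offset
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    coords = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.2, 1.3, 0.0), (3.4, 1.3, 0.3)]
    return [
        pdb_line(serial0 + i, n, "ALA", chain, res_id,
                 x + ox, y + oy, z + oz, element=e)
        for i, ((n, e), (x, y, z)) in enumerate(zip(names, coords))
    ]


def hexagon(center, radius=1.39, normal="z"):
    """Six ring-atom coordinates in a plane through ``center``."""
    ang = np.radians(np.arange(0, 360, 60))
    flat = np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)
    if normal == "x":
        flat = flat[:, [2, 0, 1]]
    elif normal == "y":
        flat = flat[:, [1, 2, 0]]
    return flat + np.asarray(center)


@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    from ivscreen.panel import clean_structure
    from ivscreen.synth import ToyComplexSpec, generate_toy_complex

    out = tmp_path_factory.mktemp("toy")
    spec = ToyComplexSpec(seed=7)
    pdb_path, sdf_path, center = generate_toy_complex(spec, out)
    receptor = clean_structure(pdb_path, pdb_id="toy")
    return {"spec": spec, "pdb": pdb_path, "sdf": sdf_path,
            "cavity_center": np.asarray(center), "receptor": receptor}


@pytest.fixture(scope="session")
def reference_report():
    from ivscreen.refscreen import reference_screen

    return reference_screen()
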