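"""FEBio 3.0 input-deck writer (and reader) for the indentation problem.

The bundled surrogate generator (:mod:`indentml.generator`) is the default
ground truth, but users with the FEBio nonlinear finite-element solver can
regenerate curves externally: :func:`write_febio_deck` emits a version-3.0
``.feb`` XML deck describing a rigid sphere of radius ``R`` displaced into
a ``W x W x H`` hexahedral block with frictionless sliding contact, the
bottom face fully fixed (bonded mounted-sample condition), and the chosen
quasi-incompressible material (``K = 1000 mu`` unless overridden).
Reaction forces harvested from the external run are read back with
:func:`read_harvest` as plain two-column text.

The mesh is deliberately coarse and regular (resolution is configurable);
convergence studies are the solver user's responsibility.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from .constitutive import Model
from .curves import IndentationCurve, SampleGeometry
from .design import DesignPoint
from .generator import DEFAULT_R

__all__ = ["write_febio_deck", "read_febio_deck", "read_harvest"]


def _block_mesh(W: float, H: float, nx: int, nz: int):
    """Regular hex mesh of the [-W/2,W/2]^2 x [-H,0] block (top at z=0)."""
    xs = np.linspace(-W / 2, W / 2, nx + 1)
    zs = np.linspace(-H, 0.0, nz + 1)
    nid = {}
    nodes = []
    k = 1
    for iz, z in enumerate(zs):
        for iy, y in enumerate(xs):
            for ix, x in enumerate(xs):
                nid[(ix, iy, iz)] = k
                nodes.append((k, x, y, z))
                k += 1
    elems = []
    e = 1
    for iz in range(nz):
        for iy in range(nx):
            for ix in range(nx):
                c = [
                    nid[(ix, iy, iz)], nid[(ix + 1, iy, iz)],
                    nid[(ix + 1, iy + 1, iz)], nid[(ix, iy + 1, iz)],
                    nid[(ix, iy, iz + 1)], nid[(ix + 1, iy, iz + 1)],
                    nid[(ix + 1, iy + 1, iz + 1)], nid[(ix, iy + 1, iz + 1)],
                ]
                elems.append((e, c))
                e += 1
    bottom = [nid[(ix, iy, 0)] for iy in range(nx + 1) for ix in range(nx + 1)]
    top_quads = [
        (nid[(ix, iy, nz)], nid[(ix + 1, iy, nz)],
         nid[(ix + 1, iy + 1, nz)], nid[(ix, iy + 1, nz)])
        for iy in range(nx) for ix in range(nx)
    ]
    return nodes, elems, bottom, top_quads


def _sphere_cap(R: float, n_theta: int = 6, n_phi: int = 12, offset: int = 0):
    """Triangulated lower cap of a sphere resting on the origin (pole at z=0)."""
    nodes = [(offset + 1, 0.0, 0.0, 0.0)]
    rings = []
    k = offset + 2
    for i in range(1, n_theta + 1):
        theta = (np.pi / 3) * i / n_theta  # 60-degree cap
        ring = []
        for j in range(n_phi):
            phi = 2 * np.pi * j / n_phi
            x = R * np.sin(theta) * np.cos(phi)
            y = R * np.sin(theta) * np.sin(phi)
            z = R * (1 - np.cos(theta))
            nodes.append((k, x, y, z))
            ring.append(k)
            k += 1
        rings.append(ring)
    tris = []
    for j in range(n_phi):
        tris.append((offset + 1, rings[0][j], rings[0][(j + 1) % n_phi]))
    for i in range(len(rings) - 1):
        a, b = rings[i], rings[i + 1]
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            tris.append((a[j], b[j], b[jn]))
            tris.append((a[j], b[jn], a[jn]))
    return nodes, tris


def _material_xml(point: DesignPoint, mat_id: int = 1) -> ET.Element:
    p = point.params
    mat = ET.Element("material", id=str(mat_id), name="sample")
    if p.model is Model.GENT:
        mat.set("type", "Gent")
        for tag, val in (("mu", p.mu), ("Jm", p.Jm), ("k", p.K)):
            ET.SubElement(mat, tag).text = repr(float(val))
    else:
        # Uncoupled neo-Hookean: Mooney-Rivlin with c2 = 0, c1 = mu/2.
        mat.set("type", "Mooney-Rivlin")
        for tag, val in (("c1", p.mu / 2), ("c2", 0.0), ("k", p.K)):
            ET.SubElement(mat, tag).text = repr(float(val))
    return mat


def write_febio_deck(
    point: DesignPoint,
    grid: NDArray[np.float64],
    path,
    *,
    R: float = DEFAULT_R,
    nx: int = 8,
    nz: int = 5,
) -> Path:
    """Write a FEBio 3.0 ``.feb`` deck for one design point.

    The rigid sphere is displaced to the last grid depth with one solver
    time step per grid increment, so the requested reaction-force output
    lands on the shared depth grid.
    """
    path = Path(path)
    grid = np.asarray(grid, dtype=float)
    W, H = point.W_over_R * R, point.H_over_R * R
    delta_max = float(grid[-1]) * R
    n_steps = max(len(grid) - 1, 1)

    root = ET.Element("febio_spec", version="3.0")
    module = ET.SubElement(root, "Module", type="solid")  # noqa: F841

    control = ET.SubElement(root, "Control")
    ET.SubElement(control, "analysis").text = "STATIC"
    ET.SubElement(control, "time_steps").text = str(n_steps)
    ET.SubElement(control, "step_size").text = repr(1.0 / n_steps)

    material = ET.SubElement(root, "Material")
    material.append(_material_xml(point, 1))
    rigid = ET.SubElement(material, "material", id="2", name="indenter", type="rigid body")
    ET.SubElement(rigid, "density").text = "1.0"

    mesh = ET.SubElement(root, "Mesh")
    nodes, elems, bottom, top_quads = _block_mesh(W, H, nx, nz)
    cap_nodes, cap_tris = _sphere_cap(R, offset=len(nodes))
    nodes_el = ET.SubElement(mesh, "Nodes", name="all")
    for k, x, y, z in nodes + cap_nodes:
        ET.SubElement(nodes_el, "node", id=str(k)).text = f"{x!r},{y!r},{z!r}"
    solid = ET.SubElement(mesh, "Elements", type="hex8", name="block")
    for e, conn in elems:
        ET.SubElement(solid, "elem", id=str(e)).text = ",".join(map(str, conn))
    shell = ET.SubElement(mesh, "Elements", type="tri3", name="indenter_cap")
    for i, tri in enumerate(cap_tris, start=len(elems) + 1):
        ET.SubElement(shell, "elem", id=str(i)).text = ",".join(map(str, tri))
    ns = ET.SubElement(mesh, "NodeSet", name="bottom")
    for k in bottom:
        ET.SubElement(ns, "n", id=str(k))
    top_surface = ET.SubElement(mesh, "Surface", name="sample_top")
    for i, quad in enumerate(top_quads, start=1):
        ET.SubElement(top_surface, "quad4", id=str(i)).text = ",".join(map(str, quad))
    ind_surface = ET.SubElement(mesh, "Surface", name="indenter_surface")
    for i, tri in enumerate(cap_tris, start=1):
        ET.SubElement(ind_surface, "tri3", id=str(i)).text = ",".join(map(str, tri))

    domains = ET.SubElement(root, "MeshDomains")
    ET.SubElement(domains, "SolidDomain", name="block", mat="sample")
    ET.SubElement(domains, "ShellDomain", name="indenter_cap", mat="indenter")

    boundary = ET.SubElement(root, "Boundary")
    fix = ET.SubElement(boundary, "bc", type="fix", node_set="bottom")
    ET.SubElement(fix, "dofs").text = "x,y,z"

    contact_el = ET.SubElement(root, "Contact")
    contact = ET.SubElement(
        contact_el, "contact", type="sliding-elastic", name="indenter_contact",
        surface_pair="contact_pair",
    )
    ET.SubElement(contact, "fric_coeff").text = "0.0"
    ET.SubElement(contact, "auto_penalty").text = "1"
    pair = ET.SubElement(mesh, "SurfacePair", name="contact_pair")
    ET.SubElement(pair, "primary").text = "sample_top"
    ET.SubElement(pair, "secondary").text = "indenter_surface"

    rigid_section = ET.SubElement(root, "Rigid")
    rc = ET.SubElement(rigid_section, "rigid_constraint", name="indent", type="prescribe")
    ET.SubElement(rc, "rb").text = "2"
    ET.SubElement(rc, "dof").text = "Rz"
    ET.SubElement(rc, "value", lc="1").text = repr(-delta_max)
    for dof in ("Rx", "Ry", "Ru", "Rv", "Rw"):
        fix_rc = ET.SubElement(
            rigid_section, "rigid_constraint", name=f"fix_{dof}", type="fix"
        )
        ET.SubElement(fix_rc, "rb").text = "2"
        ET.SubElement(fix_rc, "dofs").text = dof

    loaddata = ET.SubElement(root, "LoadData")
    lc = ET.SubElement(loaddata, "load_controller", id="1", type="loadcurve")
    ET.SubElement(lc, "interpolate").text = "LINEAR"
    pts = ET.SubElement(lc, "points")
    ET.SubElement(pts, "point").text = "0,0"
    ET.SubElement(pts, "point").text = "1,1"

    output = ET.SubElement(root, "Output")
    log = ET.SubElement(output, "logfile")
    ET.SubElement(
        log, "rigid_body_data", data="Fz", name="indenter_force",
        file=path.with_suffix(".force.txt").name,
    )

    meta = ET.SubElement(root, "Comment")
    meta.text = (
        f"W/R={point.W_over_R!r} H/R={point.H_over_R!r} R={R!r} "
        f"delta_max={delta_max!r} n_steps={n_steps}"
    )

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="ISO-8859-1")
    return path


def read_febio_deck(path) -> dict:
    """Parse a deck written by :func:`write_febio_deck` back to its inputs.

    Returns a dict with keys ``model``, ``mu``, ``Jm`` (Gent only), ``K``,
    ``W_over_R``, ``H_over_R``, ``R``, ``delta_max``, ``n_steps``.
    """
    root = ET.parse(path).getroot()
    mat = root.find("Material/material[@name='sample']")
    if mat is None:
        raise ValueError(f"{path}: no sample material block")
    out: dict = {}
    if mat.get("type") == "Gent":
        out["model"] = Model.GENT
        out["mu"] = float(mat.findtext("mu"))
        out["Jm"] = float(mat.findtext("Jm"))
        out["K"] = float(mat.findtext("k"))
    else:
        out["model"] = Model.NEO_HOOKEAN
        out["mu"] = 2.0 * float(mat.findtext("c1"))
        out["K"] = float(mat.findtext("k"))
    comment = root.findtext("Comment") or ""
    for token in comment.split():
        key, _, val = token.partition("=")
        out[{"W/R": "W_over_R", "H/R": "H_over_R"}.get(key, key)] = (
            int(val) if key == "n_steps" else float(val)
        )
    return out


def read_harvest(path, R: float, W_over_R: float, H_over_R: float) -> IndentationCurve:
    """Read externally computed (depth, force) pairs in SI units.

    The harvest format is plain two-column text (whitespace or comma
    separated, ``#`` comments): indentation depth in m, reaction force
    in N.
    """
    data = np.loadtxt(path, comments="#", delimiter=None if "," not in Path(path).read_text() else ",")
    data = np.atleast_2d(data)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (depth, force)")
    return IndentationCurve(
        np.abs(data[:, 0]), np.abs(data[:, 1]), R, SampleGeometry(R, W_over_R, H_over_R)
    )
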