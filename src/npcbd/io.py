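"""File output: XYZ snapshots, delimited tracks and tables, provenance.

All outputs are plain text and deterministic for identical inputs, and
every output directory receives the resolved configuration and seeds
needed to reproduce it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import units

_ELEMENTS = {"pom_anchor": "P", "scaffold": "C", "fg_central": "N",
             "fg_peripheral": "O", "cargo": "S"}


def write_xyz(structure, path, comment: str = "npcbd snapshot") -> None:
    """Coordinates-only snapshot in XYZ format (z = 0 plane); bead groups
    map to element symbols for generic molecular viewers."""
    lines = [str(len(structure.beads)), comment]
    for b in structure.beads:
        el = _ELEMENTS.get(b.group, "X")
        lines.append(f"{el} {b.position[0]:.6f} {b.position[1]:.6f} 0.000000")
    Path(path).write_text("\n".join(lines) + "\n")


def write_structure_tables(structure, directory) -> None:
    """Tabular bead/bond/chain listing as TSV files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = ["id\tx_nm\ty_nm\tradius_nm\tgroup\tregion\tmobile\tD_um2_s"]
    for b in structure.beads:
        rows.append(f"{b.id}\t{b.position[0]:.6f}\t{b.position[1]:.6f}"
                    f"\t{b.radius:.4f}\t{b.group}\t{b.region}"
                    f"\t{int(b.mobile)}\t{b.diffusion:.4f}")
    (d / "beads.tsv").write_text("\n".join(rows) + "\n")
    rows = ["bead_i\tbead_j\tk_s_kT_nm2\tr0_nm"]
    for bo in structure.bonds:
        rows.append(f"{bo.bead_i}\t{bo.bead_j}\t{bo.k_s:.6g}\t{bo.r0:.6f}")
    (d / "bonds.tsv").write_text("\n".join(rows) + "\n")
    rows = ["chain\tregion\tcohesive\tsegment_nm\tpersistence_nm\tbead_ids"]
    for k, c in enumerate(structure.chains):
        ids = ",".join(map(str, c.bead_ids))
        rows.append(f"{k}\t{c.region}\t{int(c.cohesive)}"
                    f"\t{c.segment_contour}\t{c.persistence}\t{ids}")
    (d / "chains.tsv").write_text("\n".join(rows) + "\n")


def write_track(record, path) -> None:
    """Per-sample cargo track: time, position, radial coordinate,
    engaged-spot count."""
    lines = ["# time_ms\tx_nm\ty_nm\tr_nm\tengaged_spots"]
    for t, (x, y), e in zip(record.times_ms, record.track,
                            record.engaged_spots):
        lines.append(f"{t:.9f}\t{x:.4f}\t{y:.4f}\t{abs(x):.4f}\t{int(e)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fpt_table(records, path) -> None:
    """One row per run: outcome, event times, first-passage time."""
    lines = ["# run\toutcome\tt_start_ms\tt_end_ms\tfpt_ms"]
    for k, r in enumerate(records):
        ts = ("" if r.t_start is None
              else f"{units.reduced_time_to_ms(r.t_start):.6f}")
        te = ("" if r.t_end is None
              else f"{units.reduced_time_to_ms(r.t_end):.6f}")
        fpt = "" if r.fpt_ms is None else f"{r.fpt_ms:.6f}"
        lines.append(f"{k}\t{r.outcome}\t{ts}\t{te}\t{fpt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_histogram(hist, path) -> None:
    """Radial histogram with its Gaussian fit echoed in the header."""
    lines = [f"# radial probability; peak={hist.peak:.3f} nm "
             f"sd={hist.sd:.3f} nm n={hist.n_samples}",
             "# r_lo_nm\tr_hi_nm\tprobability"]
    for lo, hi, p in zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                         hist.probability):
        lines.append(f"{lo:.1f}\t{hi:.1f}\t{p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(records, destination, run_config=None, structure=None
                  ) -> None:
    """Write a batch's files: per-run tracks, the aggregate FPT table,
    and (when given) the resolved config and a structure snapshot."""
    d = Path(destination)
    d.mkdir(parents=True, exist_ok=True)
    for k, r in enumerate(records):
        write_track(r, d / f"track_{k:03d}.tsv")
    write_fpt_table(records, d / "fpt.tsv")
    if structure is not None:
        write_xyz(structure, d / "structure.xyz")
        write_structure_tables(structure, d / "structure")
    if run_config is not None:
        from .config import save_config
        save_config(run_config, d / "resolved_config.yaml")


def save_checkpoint(structure, path) -> None:
    """Full positional state as TSV, sufficient to restart a run
    (topology is rebuilt deterministically from the config/seed)."""
    lines = ["# bead_id\tx_nm\ty_nm (C99 hex floats: bit-exact restart)"]
    for b in structure.beads:
        lines.append(f"{b.id}\t{float(b.position[0]).hex()}"
                     f"\t{float(b.position[1]).hex()}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_checkpoint(structure, path) -> None:
    """Restore bead positions saved by :func:`save_checkpoint`."""
    rows = [ln.split("\t") for ln in Path(path).read_text().splitlines()
            if ln and not ln.startswith("#")]
    if len(rows) != len(structure.beads):
        raise ValueError(f"checkpoint has {len(rows)} beads, "
                         f"structure has {len(structure.beads)}")
    for bid, x, y in rows:
        structure.beads[int(bid)].position = np.array(
            [float.fromhex(x), float.fromhex(y)])
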