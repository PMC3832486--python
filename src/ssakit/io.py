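"""Explicit-output file format and run manifests.

The on-disk trajectory format is a tab-separated table mirroring the
explicit-output layout: one row per event with the event time, the fired
reaction index, every species copy number, and every reaction propensity::

    time    fired   <species...>    a_<reaction...>

The fired column holds the reaction index (−1 for the initial row, −2 for
a time-mode terminal marker row).  Times and propensities are written with
17 significant digits ('.' decimal separator) so a round trip is lossless.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .trajectory import Trajectory

__all__ = ["write_explicit_tsv", "read_explicit_tsv", "write_manifest", "TsvFormatError"]


class TsvFormatError(ValueError):
    pass


def write_explicit_tsv(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory to the explicit-output TSV layout (lossless)."""
    path = Path(path)
    cols = (
        ["time", "fired"]
        + list(trajectory.species_names)
        + [f"a_{name}" for name in trajectory.reaction_names]
    )
    with open(path, "w") as fh:
        fh.write("# ssakit explicit output\n")
        fh.write(f"# model: {trajectory.model_ref}\n")
        fh.write(f"# exact: {int(trajectory.exact)}\tabsorbed: {int(trajectory.absorbed)}\n")
        fh.write("\t".join(cols) + "\n")
        for k in range(len(trajectory.times)):
            fields = [f"{trajectory.times[k]:.17g}", str(int(trajectory.fired[k]))]
            fields += [str(int(v)) for v in trajectory.states[k]]
            fields += [f"{v:.17g}" for v in trajectory.propensities[k]]
            fh.write("\t".join(fields) + "\n")


def read_explicit_tsv(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_explicit_tsv`.

    Raises :class:`TsvFormatError` with the offending row number on schema
    violations (wrong column count, non-increasing times, negative copies).
    """
    path = Path(path)
    model_ref = "model"
    exact, absorbed = True, False
    header: list[str] | None = None
    times, states, props, fired = [], [], [], []
    n_species = n_reactions = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("model:"):
                    model_ref = body.split(":", 1)[1].strip()
                elif body.startswith("exact:"):
                    parts = dict(
                        p.split(":") for p in body.replace(" ", "").split("\t")
                    )
                    exact = bool(int(parts.get("exact", "1")))
                    absorbed = bool(int(parts.get("absorbed", "0")))
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["time", "fired"]:
                    raise TsvFormatError(
                        f"row {lineno}: header must start with 'time\\tfired'"
                    )
                prop_cols = [c for c in header if c.startswith("a_")]
                n_reactions = len(prop_cols)
                n_species = len(header) - 2 - n_reactions
                if n_species < 1:
                    raise TsvFormatError(f"row {lineno}: no species columns")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise TsvFormatError(
                    f"row {lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            try:
                t = float(fields[0])
                f = int(fields[1])
                s = [int(v) for v in fields[2 : 2 + n_species]]
                a = [float(v) for v in fields[2 + n_species :]]
            except ValueError as exc:
                raise TsvFormatError(f"row {lineno}: {exc}") from exc
            if times and t < times[-1]:
                raise TsvFormatError(f"row {lineno}: decreasing time {t}")
            if times and t == times[-1] and f != -2:
                raise TsvFormatError(f"row {lineno}: duplicate event time {t}")
            if any(v < 0 for v in s):
                raise TsvFormatError(f"row {lineno}: negative copy number")
            times.append(t)
            fired.append(f)
            states.append(s)
            props.append(a)
    if header is None or not times:
        raise TsvFormatError("file contains no trajectory rows")
    species_names = header[2 : 2 + n_species]
    reaction_names = [c[2:] for c in header[2 + n_species :]]
    return Trajectory(
        times=np.array(times),
        states=np.array(states, dtype=np.int64),
        propensities=np.array(props),
        fired=np.array(fired, dtype=np.int64),
        species_names=species_names,
        reaction_names=reaction_names,
        exact=exact,
        absorbed=absorbed,
        model_ref=model_ref,
    )


def write_manifest(path: str | Path, model_text: str, **fields) -> None:
    """Write a key-value run manifest including a model content hash.

    The manifest plus the seed fully determine a run's outputs.
    """
    import numpy

    path = Path(path)
    digest = hashlib.sha256(model_text.encode()).hexdigest()
    from . import __version__

    lines = [f"model_sha256 = {digest}",
             f"ssakit_version = {__version__}",
             f"numpy_version = {numpy.__version__}"]
    for key, value in fields.items():
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")
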