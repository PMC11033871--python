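"""Shared fixtures: small toy cascade runs and helper builders."""

import textwrap
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from pacsmd.config_io import config_from_dict, write_structure
from pacsmd.dynamics import DoubleWell1D
from pacsmd.engine import run_trial
from pacsmd.units import KB

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def write_toy_mdconf(path: Path, *, system: str = "double_well_1d",
                     system_kwargs: dict | None = None, dt: float = 0.01,
                     n_steps: int = 200, save_interval: int = 10,
                     temperature: float = 300.0,
                     friction: float = 1.0) -> Path:
    lines = ["[system]", f'name = "{system}"']
    for key, value in (system_kwargs or {}).items():
        lines.append(f"{key} = {value}")
    lines += ["", "[md]", f"dt = {dt}", f"n_steps = {n_steps}",
              f"save_interval = {save_interval}",
              f"temperature = {temperature}", f"friction = {friction}"]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_trial(tmp_path_factory):
    """A completed targeted-cascade trial on the 1-D double well:
    3 replicas, cycles 0..3 (stops at max_cycle), 10 trajectories."""
    root = tmp_path_factory.mktemp("toy_trial")
    mdconf = write_toy_mdconf(
        root / "md.toml",
        system_kwargs={"barrier": 8 * KB * 300, "half_separation": 1.0})
    ref = DoubleWell1D().to_snapshot(np.array([[1.0]]))
    write_structure(ref, root / "ref.pdb")
    cfg = config_from_dict(dict(
        simulator="toy", type="target", n_replica=3, max_cycle=3,
        threshold=0.02, selection1="all", selection2="all",
        reference=str(root / "ref.pdb"), mdconf=str(mdconf),
        trial=1, seed=11))
    state = run_trial(cfg, root=root)
    return cfg, root, state


@pytest.fixture()
def toy_config_file(tmp_path):
    """A valid on-disk TOML configuration plus its mdconf and reference."""
    mdconf = write_toy_mdconf(tmp_path / "md.toml", n_steps=50)
    ref = DoubleWell1D().to_snapshot(np.array([[1.0]]))
    write_structure(ref, tmp_path / "ref.pdb")
    cfg_path = tmp_path / "input.toml"
    cfg_path.write_text(textwrap.dedent(f"""\
        simulator = "toy"
        type = "target"
        n_replica = 2
        max_cycle = 2
        threshold = 0.05
        selection1 = "all"
        selection2 = "all"
        reference = "{tmp_path / 'ref.pdb'}"
        mdconf = "{tmp_path / 'md.toml'}"
        trial = 1
        seed = 5
        """))
    return cfg_path
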