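"""Run configuration with the reference umbrella-sampling defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Defaults mirror the reference 2D umbrella setup.

    13 flipping windows over [-100, 100] deg crossed with 24 glycosidic
    windows over [-180, 180] deg (312 windows), force constants 100 and 50
    kcal/mol/rad^2, 300 K, 5-degree analysis bins.
    """

    temperature: float = 300.0
    n_cpdb: int = 13
    cpdb_range: tuple = (-100.0, 100.0)
    n_chi: int = 24
    chi_range: tuple = (-180.0, 180.0)
    k_cpdb: float = 100.0
    k_chi: float = 50.0
    bin_width: float = 5.0
    wham_tol: float = 1e-7
    wham_max_iter: int = 100_000
    flip_small_cutoff: float = 20.0   # degrees, small-flip route band
    flip_large_cutoff: float = 60.0   # degrees, opened-base region
    seed: int = 0
    n_steps: int = 16_000
    n_equil: int = 1_000
    thin: int = 5
    convergence_fractions: tuple = (0.25, 0.5, 0.75, 1.0)
    output_dir: str = "hgflip_out"

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("cpdb_range", "chi_range", "convergence_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))
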