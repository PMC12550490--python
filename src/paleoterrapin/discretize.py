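"""Log-spaced coalescent-time discretization and free-interval patterns.

Time (units of 2*N0 generations) is cut into ``n_atomic`` intervals whose
edges follow t_k = 0.1*(exp((k/n)*ln(1+10*t_max)) - 1); the last interval
is unbounded.  A pattern string such as "2+2+25*2+4+6" groups atomic
intervals into free intervals that share one coalescence-rate parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def expand_pattern(pattern: str, n_atomic: int) -> list[int]:
    """Expand "a" / "m*a" tokens to per-free-interval atomic counts."""
    counts: list[int] = []
    for token in pattern.replace(" ", "").split("+"):
        if not token:
            raise ValueError("empty token in pattern")
        if "*" in token:
            m, a = token.split("*")
            counts.extend([int(a)] * int(m))
        else:
            counts.append(int(token))
    if any(c <= 0 for c in counts):
        raise ValueError("atomic counts must be positive")
    if sum(counts) != n_atomic:
        raise ValueError(f"pattern covers {sum(counts)} atomic intervals, expected {n_atomic}")
    return counts


@dataclass
class TimeDiscretization:
    n_atomic: int = 64
    pattern: str = "2+2+25*2+4+6"
    t_max: float = 15.0
    group_sizes: list[int] = field(init=False)
    atomic_to_free: np.ndarray = field(init=False)
    boundaries: np.ndarray = field(init=False)  # length n_atomic + 1, last = inf

    def __post_init__(self) -> None:
        self.group_sizes = expand_pattern(self.pattern, self.n_atomic)
        self.atomic_to_free = np.repeat(np.arange(len(self.group_sizes)), self.group_sizes)
        k = np.arange(self.n_atomic + 1)
        edges = 0.1 * (np.exp((k / self.n_atomic) * np.log(1 + 10 * self.t_max)) - 1.0)
        edges[-1] = np.inf
        self.boundaries = edges

    @property
    def n_free(self) -> int:
        return len(self.group_sizes)

    def lam_atomic(self, lam_free: np.ndarray) -> np.ndarray:
        """Per-atomic-interval coalescence rates from free-interval values."""
        return np.asarray(lam_free, dtype=float)[self.atomic_to_free]

    def free_left_edges(self) -> np.ndarray:
        """Left time boundary of each free interval (coalescent units)."""
        starts = np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]])
        return self.boundaries[starts]


def parse_pattern(pattern: str, n_atomic: int = 64, t_max: float = 15.0) -> TimeDiscretization:
    return TimeDiscretization(n_atomic=n_atomic, pattern=pattern, t_max=t_max)
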