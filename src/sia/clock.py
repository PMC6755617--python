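"""Injectable time source so retry delays and TTLs are testable.

All pipeline components take a :class:`Clock` instead of calling
``time.time``/``time.sleep`` directly; tests substitute :class:`FakeClock`
and assert on the recorded sleeps without real waiting.
"""

from __future__ import annotations

import time
from typing import Protocol


class Clock(Protocol):
    def now(self) -> float:
        """Current POSIX timestamp (UTC seconds)."""
        ...

    def sleep(self, seconds: float) -> None: ...


class SystemClock:
    """Wall-clock implementation used in production."""

    def now(self) -> float:
        return time.time()

    def sleep(self, seconds: float) -> None:
        time.sleep(seconds)


class FakeClock:
    """Deterministic clock: ``sleep`` advances time and records the delay."""

    def __init__(self, start: float = 0.0):
        self._now = float(start)
        self.sleeps: list[float] = []

    def now(self) -> float:
        return self._now

    def sleep(self, seconds: float) -> None:
        self.sleeps.append(seconds)
        self._now += seconds

    def advance(self, seconds: float) -> None:
        self._now += seconds
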