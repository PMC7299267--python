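"""Line-delimited structured run log.

Every non-default decision the pipeline takes (format dialects detected,
date conversions, dropped cohorts or covariates, seeds) is recorded as
one JSON object per line so a run can be audited afterwards.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path


class RunLog:
    """Append-only JSONL event log; with no path it collects in memory."""

    def __init__(self, path=None):
        self.path = Path(path) if path is not None else None
        self.events: list[dict] = []

    def event(self, kind: str, **fields) -> None:
        record = {
            "time": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            "event": kind,
            **fields,
        }
        self.events.append(record)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps(record) + "\n")
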