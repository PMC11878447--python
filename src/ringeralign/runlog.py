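"""Machine-readable run records as JSON lines.

Every pipeline run appends timestamped events (configuration echo, tool
versions, skipped-row counts, alignment engine and parameters, stage
failures) to a ``run_log.jsonl`` so an analysis can be audited and
reproduced later.
"""

from __future__ import annotations

import json
import sys
from datetime import datetime, timezone
from pathlib import Path


class RunLog:
    def __init__(self, path: str | Path | None, echo_stderr: bool = False):
        self.path = Path(path) if path is not None else None
        self.echo_stderr = echo_stderr
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)

    def event(self, kind: str, **fields) -> None:
        rec = {"ts": datetime.now(timezone.utc).isoformat(), "event": kind}
        rec.update(fields)
        line = json.dumps(rec, sort_keys=True, default=str)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
        if self.echo_stderr:
            print(line, file=sys.stderr)
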