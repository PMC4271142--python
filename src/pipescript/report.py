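"""Execution report: a machine-readable JSON file plus a self-contained
HTML page with a task timeline.  Written even when the run fails, since
the report's main job is debugging: every task record carries its state,
attempt count, exit code and log paths."""

from __future__ import annotations

import html
import json
import os
import time


def build_report(engine) -> dict:
    tasks = []
    with engine.scheduler.lock:
        records = list(engine.scheduler.records.values())
    for rec in sorted(records, key=lambda r: r.spec.id):
        tasks.append({
            "id": rec.spec.id,
            "name": rec.spec.name,
            "state": rec.state,
            "cpus": rec.spec.cpus,
            "attempts": rec.attempts,
            "exit_code": rec.exit_code,
            "t_sched": rec.t_sched,
            "t_start": rec.t_start,
            "t_end": rec.t_end,
            "stdout": rec.stdout_path,
            "stderr": rec.stderr_path,
            "failure_reason": rec.failure_reason,
            "ins": rec.spec.ins,
            "outs": rec.spec.outs,
        })
    events = [{"t": t, "id": i, "old": o, "new": n}
              for t, i, o, n in engine.events.snapshot()]
    t_values = [e["t"] for e in events] or [time.time()]
    return {
        "script": engine.script_path,
        "run_dir": engine.run_dir,
        "t_begin": min(t_values),
        "t_end": max(t_values),
        "tasks": tasks,
        "par_threads": {pid: rec["status"]
                        for pid, rec in engine.par_records.items()},
        "events": events,
    }


_STATE_COLORS = {
    "DONE": "#4caf50", "FAILED": "#e53935", "TIMEOUT": "#fb8c00",
    "KILLED": "#757575", "SKIPPED": "#90caf9", "RUNNING": "#fdd835",
}


def render_html(report: dict) -> str:
    t0 = report["t_begin"]
    span = max(report["t_end"] - t0, 1e-6)
    rows = []
    for task in report["tasks"]:
        color = _STATE_COLORS.get(task["state"], "#bdbdbd")
        if task["t_start"] and task["t_end"]:
            left = 100.0 * (task["t_start"] - t0) / span
            width = max(0.5, 100.0 * (task["t_end"] - task["t_start"]) / span)
            bar = (f'<div class="bar" style="margin-left:{left:.2f}%;'
                   f'width:{width:.2f}%;background:{color}"></div>')
        else:
            bar = f'<span class="tag" style="background:{color}">{task["state"]}</span>'
        name = html.escape(task["name"] or "")
        rows.append(
            f"<tr><td>{html.escape(task['id'])}</td><td>{name}</td>"
            f"<td>{task['state']}</td><td>{task['cpus']}</td>"
            f"<td>{task['attempts']}</td><td>{task['exit_code']}</td>"
            f'<td class="timeline">{bar}</td></tr>')
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>pipeline report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; width: 100%; }}
td, th {{ border: 1px solid #ddd; padding: 4px 8px; font-size: 13px; }}
.timeline {{ width: 45%; position: relative; }}
.bar {{ height: 12px; border-radius: 2px; }}
.tag {{ padding: 1px 6px; border-radius: 2px; font-size: 11px; }}
</style></head><body>
<h1>Pipeline execution report</h1>
<p>script: <code>{html.escape(report['script'])}</code><br>
run directory: <code>{html.escape(report['run_dir'])}</code><br>
wall time: {report['t_end'] - report['t_begin']:.2f} s</p>
<table>
<tr><th>id</th><th>name</th><th>state</th><th>cpus</th><th>attempts</th>
<th>exit</th><th>timeline</th></tr>
{''.join(rows)}
</table></body></html>
"""


def write_report(engine) -> tuple:
    report = build_report(engine)
    json_path = os.path.join(engine.run_dir, "report.json")
    html_path = os.path.join(engine.run_dir, "report.html")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(html_path, "w", encoding="utf-8") as fh:
        fh.write(render_html(report))
    return json_path, html_path
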