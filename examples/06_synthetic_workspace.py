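"""Materialize a demo workspace and run the full pipeline over its files.

`make_fixture_workspace` writes both phase cohorts, unit costs, the DDD
reference and the staffing rosters as plain delimited text; `run_analysis`
reads them back, filters, costs, compares, tests and runs the Monte Carlo,
writing a deterministic report bundle.  The same flow is available from
the shell: `stewardcost simulate` then `stewardcost analyze`.
"""

import tempfile
from pathlib import Path

from stewardcost import make_fixture_workspace
from stewardcost.workflow import RunConfig, run_analysis

root = Path(tempfile.mkdtemp())
paths = make_fixture_workspace(root / "workspace", seed=7)
print("workspace files:")
for name, path in sorted(paths.items()):
    print(f"  {name}: {path.relative_to(root)}")

reports = run_analysis(RunConfig(
    cohort_preliminary=paths["preliminary"],
    cohort_developed=paths["developed"],
    unit_costs=paths["unit_costs"],
    ddd_reference=paths["ddd_reference"],
    staffing=paths["staffing"],
    output_dir=root / "reports",
    seed=7,
    log_level="WARNING",
))
print()
print("report bundle:")
for name, path in sorted(reports.items()):
    print(f"  {name}: {path.relative_to(root)}")
print()
print((root / "reports" / "report.md").read_text().split("## Cost-benefit")[1][:60])
print("(see report.md for the full two-currency tables)")
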