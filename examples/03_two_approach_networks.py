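"""The two nonstationarity-aware network approaches on a hard case.

Simulates a person whose symptoms covary ONLY through a shared recovery
trend and a shared 24-hr cycle (identity residual precision).  Approach 1
embeds the temporal terms as network nodes; approach 2 detrends each
symptom and models the residuals.  The residual network should come out
empty: once time is removed there is no symptom covariation left.
"""

import numpy as np

from emanet import GroundTruth, RunConfig, SimConfig, run_person, simulate_person
from emanet.synthetic_data import _scale_trend_cycles_to_r2

p = 8
truth = GroundTruth(
    symptoms=tuple(f"S{i}" for i in range(p)),
    trend=np.tile([-1.0, 0.3, 0.0], (p, 1)),  # shared recovery shape
    amp24=np.full(p, 1.0), phase24=np.full(p, 0.8),  # shared diurnal cycle
    amp12=np.zeros(p), phase12=np.zeros(p),
    baseline=np.full(p, 2.5),
    precision=np.eye(p),  # no residual (contemporaneous) structure at all
    noise_sd=np.ones(p),
)
truth = _scale_trend_cycles_to_r2(truth, SimConfig(), np.full(p, 0.45))

ds, meta = simulate_person(truth, SimConfig(), seed=11, person_id="analog")
res = run_person(ds, RunConfig(seed=11))

raw, det = res.network_raw, res.network_detrended
sym = [i for i, k in enumerate(raw.kinds) if k == "symptom"]
tmp = [i for i, k in enumerate(raw.kinds) if k == "temporal"]
st = sum(1 for i in sym for j in tmp if raw.W[i, j] != 0)
ss = sum(1 for a, i in enumerate(sym) for j in sym[a + 1:] if raw.W[i, j] != 0)

print(f"embedded network (approach 1): {len(raw.nodes)} nodes "
      f"({len(sym)} symptom + {len(tmp)} temporal)")
print(f"  symptom-temporal edges: {st}   <- the trends/cycles in each symptom")
print(f"  symptom-symptom edges : {ss}   <- weak leftovers of sampling noise")
print(f"residual network (approach 2): {det.n_edges} edges "
      f"{'(empty)' if det.is_empty else ''}")
print(
    "\nAn empty residual network says all symptom covariation was carried "
    "by shared temporal structure - the detrending removed it entirely."
)
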