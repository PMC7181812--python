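"""Score one stock with every method under the shared evaluation protocol.

Twenty-five target years are drawn once per stock; each stock-recruitment
model is refitted on that target's 24-point training set (predecessor year
included) and scored by the Pearson correlation between observed and
predicted recruitment. The EDM search scores the same targets, maximizing
over all 63 delay embeddings and the theta grid.
"""

import recruitcast as rc
from recruitcast.crossval import EvaluationProtocol, select_targets, training_set

truth = rc.simulate_truth(rc.OperatingModelParams(seed=4, n_years=40))
stock = rc.make_direct_data(truth, sigma_obs=0.2, seed=5)

protocol = EvaluationProtocol()
rng = rc.stock_rng(7, stock.stock_id)
targets = select_targets(stock.n_years, protocol, rng)
training = {int(t): training_set(int(t), stock.n_years, protocol, rng) for t in targets}
print(f"{stock.n_years}-year stock, {len(targets)} evaluation targets")

for kind in ("density_independent", "ricker", "beverton_holt"):
    res = rc.loocv_sfm(stock, kind, protocol, rng, targets=targets, training_sets=training)
    print(f"{kind:>20}: rho = {res.rho:.3f} over {res.n_targets_used} targets")

edm = rc.best_edm_rho(stock, target_times=targets)
print(
    f"{'edm':>20}: rho = {edm.rho:.3f} using {edm.best_spec} "
    f"at theta={edm.best_theta}"
)
# Higher rho = better one-step recruitment forecasts at the shared targets.
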