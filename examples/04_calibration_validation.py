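"""Calibrate model predictions against the Hannover harvest statistics.

Uses the packaged 27-year observed/predicted series for silage maize and
winter wheat and prints the validation report (adjustment factor, RMSE,
percent error, correlation, Willmott index of agreement).
"""
from biopotential import build_report, load_hannover_yields

df = load_hannover_yields()
for crop, obs, pred in (
    ("maize", df.maize_obs, df.maize_pred),
    ("winter wheat", df.wheat_obs, df.wheat_pred),
):
    rep = build_report(obs, pred, crop=crop)
    f = rep.footer()
    print(
        f"{crop:12s} factor={f['factor']:.2f}  RMSE={f['rmse']} dt/ha  "
        f"error={f['overall_error_pct']}%  r={f['pearson_r']} (p={rep.p_value:.1e})  "
        f"d={f['willmott_d']}"
    )
print("\nThe factor (mean observed / mean predicted) corrects the systematic")
print("field-vs-trial yield gap; the remaining scatter is summarised by RMSE,")
print("its percent error, the correlation and the Willmott index.")
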