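"""Build the 230-trial gambling task and inspect its structure."""

from lossaversion.task_design import assemble_task

task = assemble_task(seed=0)
df = task.to_dataframe()

print("trials:", len(task), "by condition:", task.condition_counts())

gain = df[df.condition == "gain"]
ratios = gain[["gamble_out1", "gamble_out2"]].max(axis=1) / gain["sure"]
print(f"gain-trial gamble/sure ratios: {ratios.min():.2f} .. {ratios.max():.2f}")

mixed = df[df.condition == "mixed"]
print("mixed gains:", sorted(int(g) for g in
                             mixed[["gamble_out1", "gamble_out2"]]
                             .max(axis=1).unique()))
print(f"mean ITI: {df.iti_s.mean():.2f} s, task duration: "
      f"{df.onset_s.iloc[-1] / 60:.1f} min")

# The task crosses gains {8..30} with losses {-5..-27} in the 144 mixed
# trials (a full 12 x 12 factorial, so gain and loss magnitudes are
# uncorrelated by design), flanks them with 40 gain-only, 40 mirrored
# loss-only and 6 catch trials, and jitters inter-trial intervals on
# 4-8 s.
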