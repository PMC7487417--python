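"""Train a 10 x 10 associative memory on 10 patterns and recall them.

Each pattern clamps one winning minicolumn per hypercolumn for 500 ms of
teacher-forced training; recall then cues each pattern for 30 ms and lets
the network free-run for 70 ms.  The recall accuracy is the fraction of
hypercolumns whose soft-WTA winner matches the trained target (chance
level is 1/M = 0.1).
"""

from bcpnn_cue import SimulationConfig
from bcpnn_cue.activity import PatternSchedule
from bcpnn_cue.io import make_patterns
from bcpnn_cue.strategies import Simulation

cfg = SimulationConfig(n_hcu=10, n_mcu=10, seed=13)
train = make_patterns(cfg.n_hcu, cfg.n_mcu, n_patterns=10, duration=500, seed=3)

sim = Simulation(cfg)
res = sim.run(train)
print(f"training: {res.raster.sum()} spikes over {train.n_steps} steps, "
      f"{res.ledger.n_row_events} row updates, {res.ledger.n_col_events} column updates")

correct = total = 0
for pat, _ in train.entries:
    recall = PatternSchedule([(pat, 30), (None, 70)], training=True)
    r = sim.run(recall)
    correct += int((r.winners[-1] == pat).sum())
    total += pat.size
print(f"recall accuracy: {correct / total:.2f}  (chance level 1/M = {1 / cfg.n_mcu})")
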