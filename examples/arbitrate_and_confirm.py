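"""Protocol arbitration and the fading feedback rule.

Trains the correlation-space selector, classifies windows from each
condition, and traces the fading rule through a noisy classification
stream to show how commands are confirmed (and idle noise suppressed).
"""

from hybridbci.closedloop import train_decoders
from hybridbci.hybrid import Command, classify_window, run_fading
from hybridbci.synth import SynthConfig, gen_erd_trials, gen_ssvep_trials


def main():
    dec = train_decoders(seed=3)
    conditions = {
        "12 Hz flicker": gen_ssvep_trials(SynthConfig(seed=70, snr=3.0),
                                          12.0, 1).windows[0],
        "15 Hz flicker": gen_ssvep_trials(SynthConfig(seed=71, snr=3.0),
                                          15.0, 1).windows[0],
        "motor imagery": gen_erd_trials(SynthConfig(seed=72, snr=3.0), 1, 0,
                                        attenuation=0.9).windows[0],
        "rest": gen_erd_trials(SynthConfig(seed=73, snr=3.0), 0, 1,
                               attenuation=0.9).windows[0],
    }
    print("per-window classification (one decision per 250 ms):")
    for name, w in conditions.items():
        cmd = classify_window(dec.selector, dec.csp, dec.erd_clf, w)
        print(f"  {name:14s} -> {cmd.value}")

    L, R = Command.HEAD_LEFT, Command.HEAD_RIGHT
    stream = [L, L, R, R, R, R, R, R, R]
    _, confirmed = run_fading(stream)
    names = [c.value for c in stream]
    print(f"\nfading rule on {names}:")
    for idx, cmd in confirmed:
        print(f"  confirmed {cmd.value} on input {idx + 1} "
              f"({idx * 0.25:.2f} s after the first)")
    print("a command needs four consecutive agreements beyond adoption "
          "(1.0 s minimum); disagreements bleed the selection level, so "
          "isolated misclassifications never reach the robot.")


if __name__ == "__main__":
    main()
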