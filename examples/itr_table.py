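"""Wolpaw information transfer rate from accuracy, classes and rate.

Tabulates bits/min for a 2-class decoder at one decision per 2 s window
(30 decisions/min) over a range of accuracies, the regime of the
navigation protocols.
"""

from hybridbci.evaluation import wolpaw_itr


def main():
    print("accuracy  ITR (bits/min, N=2, 30 decisions/min)")
    for acc in (0.5, 0.6, 0.7, 0.768, 0.8, 0.875, 0.9, 0.922, 1.0):
        print(f"  {100 * acc:5.1f}%   {wolpaw_itr(acc, 2, 30):5.1f}")
    print("chance level (50%) carries no information; each decision of a "
          "perfect decoder carries one full bit, hence 30 bits/min.")


if __name__ == "__main__":
    main()
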