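"""Independent oracles shared by test modules."""

import numpy as np


def explicit_inverse_recovery(model, indices):
    """Weight recovery by literal inverse mapping, for cross-checking.

    For each block k and bin b, every minhash value t with h(t) = b is
    pulled back through the inverse permutation pi_k^-1 to an original
    feature index, which receives the bin's weight w[k*N + b]; each
    feature's recovered weight is its average contribution over the ell
    blocks.  Exponential in nothing but brutally explicit — usable only
    for small universes.
    """
    fam = model.family
    acc = {int(i): 0.0 for i in indices}
    for k in range(fam.ell):
        perm = fam.permutation(k)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        all_t = np.arange(fam.value_range)
        bins = np.asarray(fam.additional_hash(all_t))
        for b in range(fam.N):
            for t in all_t[bins == b]:
                original = int(inv[t])
                if original in acc:
                    acc[original] += float(model.weights[k * fam.N + b])
    return {i: v / fam.ell for i, v in acc.items()}
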