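from repeatsig.align import MutationProfile, ProfileEntry


def profile_of(sample_id, entries, label=None):
    """Build a MutationProfile from (pattern, m, d) tuples on one contig."""
    es = [
        ProfileEntry("chr1", 100 * i, 100 * i + 10, p, m, d)
        for i, (p, m, d) in enumerate(entries)
    ]
    return MutationProfile(sample_id, es, label)
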