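"""Small shared helpers for building test fixtures programmatically."""

from mmnet import MembershipMap, build_weight_matrix


def membership_map(member_index, k, name="m"):
    n = len(member_index)
    groups = [set() for _ in range(k)]
    for i, ms in enumerate(member_index):
        for j in ms:
            groups[j].add(i)
    return MembershipMap(
        classification_name=name,
        node_ids=tuple(range(n)),
        groups=tuple(frozenset(g) for g in groups),
        group_labels=tuple(range(k)),
    )


def membership_weight_matrix(member_index, k, scheme="equal", name="m"):
    return build_weight_matrix(membership_map(member_index, k, name), scheme)
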