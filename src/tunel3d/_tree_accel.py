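"""Compiled inner loops for the component tree (numba).

These are pure index-shuffling kernels: subtree accumulation in
topological order and an iterative Euler-tour DFS that lays every
node's support out as a contiguous pixel slice.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def max_tree_parents(vals, sort_asc, nz, ny, nx, offsets):
    """Canonicalized max-tree parent image by union-find.

    ``sort_asc`` orders flat pixel indices by ascending value (stable);
    pixels are processed in descending order, merging each pixel with
    already-processed neighbours (Berger-style union-find with path
    compression), then parents are canonicalized so that every
    non-canonical pixel points at its component's canonical pixel.
    ``sort_asc`` itself is a valid traversal order (parents first).
    """
    n = vals.size
    parent = np.full(n, -1, np.int64)
    zpar = np.empty(n, np.int64)
    plane = ny * nx
    for i in range(n - 1, -1, -1):
        p = sort_asc[i]
        parent[p] = p
        zpar[p] = p
        z = p // plane
        rem = p - z * plane
        y = rem // nx
        x = rem - y * nx
        for k in range(offsets.shape[0]):
            z2 = z + offsets[k, 0]
            y2 = y + offsets[k, 1]
            x2 = x + offsets[k, 2]
            if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                q = (z2 * ny + y2) * nx + x2
                if parent[q] != -1:
                    r = q
                    while zpar[r] != r:
                        r = zpar[r]
                    s = q
                    while zpar[s] != r:
                        t = zpar[s]
                        zpar[s] = r
                        s = t
                    if r != p:
                        parent[r] = p
                        zpar[r] = p
    for i in range(n):  # ascending: a pixel's parent is canonicalized first
        p = sort_asc[i]
        q = parent[p]
        if vals[parent[q]] == vals[q]:
            parent[p] = parent[q]
    return parent


@njit(cache=True)
def push_up(topo_order, node_parent, values):
    """Accumulate child values into parents; ``topo_order`` lists parents first."""
    for i in range(topo_order.shape[0] - 1, -1, -1):
        c = topo_order[i]
        p = node_parent[c]
        if p != c:
            values[p] += values[c]


@njit(cache=True)
def euler_tour(node_parent, children, child_off, grp_pix, grp_start, grp_end, root):
    """Pre-order DFS producing contiguous per-subtree pixel intervals.

    Returns (euler, start, end, pre_order): pixel flat indices laid out
    so that node ``c``'s full support is ``euler[start[c]:end[c]]``.
    """
    k = node_parent.shape[0]
    n = grp_pix.shape[0]
    euler = np.empty(n, np.int64)
    start = np.empty(k, np.int64)
    end = np.empty(k, np.int64)
    pre = np.empty(k, np.int64)
    stack_node = np.empty(k + 1, np.int64)
    stack_child = np.empty(k + 1, np.int64)

    pos = 0
    out = 0
    top = 0
    stack_node[0] = root
    stack_child[0] = child_off[root]
    pre[out] = root
    out += 1
    start[root] = pos
    for j in range(grp_start[root], grp_end[root]):
        euler[pos] = grp_pix[j]
        pos += 1
    while top >= 0:
        node = stack_node[top]
        ci = stack_child[top]
        if ci < child_off[node + 1]:
            stack_child[top] = ci + 1
            ch = children[ci]
            pre[out] = ch
            out += 1
            start[ch] = pos
            for j in range(grp_start[ch], grp_end[ch]):
                euler[pos] = grp_pix[j]
                pos += 1
            top += 1
            stack_node[top] = ch
            stack_child[top] = child_off[ch]
        else:
            end[node] = pos
            top -= 1
    return euler, start, end, pre


@njit(cache=True)
def subtree_max(pre_order, node_parent, score, candidate, sub_max):
    """Best candidate score within each node's subtree (self included)."""
    for i in range(pre_order.shape[0] - 1, -1, -1):
        node = pre_order[i]
        if candidate[node] and score[node] > sub_max[node]:
            sub_max[node] = score[node]
        p = node_parent[node]
        if p != node and sub_max[node] > sub_max[p]:
            sub_max[p] = sub_max[node]


@njit(cache=True)
def select_top_down(pre_order, node_parent, score, candidate, sub_max, tol, root, selected):
    """Select the largest candidate within ``tol`` of its subtree's best score.

    Pre-order walk; a selected node blocks its whole subtree, so the
    selection is pairwise disjoint.
    """
    blocked = np.zeros(selected.shape[0], np.bool_)
    for i in range(pre_order.shape[0]):
        node = pre_order[i]
        p = node_parent[node]
        if node != root and (blocked[p] or selected[p]):
            blocked[node] = True
            continue
        if candidate[node] and score[node] >= sub_max[node] - tol:
            selected[node] = True
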