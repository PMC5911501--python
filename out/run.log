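2026-09-28 22:03:16,097 INFO config /tmp/pytest-of-root/pytest-7/test_missing_mesh_file_names_p0/missing.toml (hash 3630f2b82dec838b), seed 0
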