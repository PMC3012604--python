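>hFKBP12 human FK506-binding protein 12 (accession A35780)
MGVQVETISPGDGRTFPKRGQTCVVHYTGMLEDGKKFDSSRDRNKPFKFMLGKQEVIRGW
EEGVAQMSVGQRAKLTISPDYAYGATGHPGIIPPHATLVFDVELLKLE
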